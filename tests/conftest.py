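import numpy as np
import pytest

from junctomech.coilscan import (
    ResidueChain,
    ResidueClassScheme,
    axial_positions,
    classify_residue,
)


def brute_force_interactions(
    chain_a: ResidueChain,
    chain_b: ResidueChain,
    orientation: str,
    stagger: int,
    scheme: ResidueClassScheme | None = None,
) -> tuple[int, int, int]:
    """Independent exhaustive double-loop oracle for pair counting."""
    scheme = scheme or ResidueClassScheme()
    pos_a, pos_b, overlap = axial_positions(chain_a, chain_b, orientation, stagger)
    seq_a, seq_b = chain_a.cc_sequence, chain_b.cc_sequence
    n_apolar = n_ionic = 0
    for i, xa in pos_a.items():
        for j, xb in pos_b.items():
            d = abs(xa - xb)
            ca = classify_residue(seq_a[i - 1], scheme)
            cb = classify_residue(seq_b[j - 1], scheme)
            if ca == cb == "apolar" and d <= scheme.apolar_window:
                n_apolar += 1
            if {ca, cb} == {"acidic", "basic"} and d <= scheme.ionic_window:
                n_ionic += 1
    return n_apolar, n_ionic, overlap


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_chain(rng, length, id_="x") -> ResidueChain:
    aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seq = "".join(rng.choice(aas, size=length))
    return ResidueChain(id=id_, sequence=seq, cc_span=(1, length))
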