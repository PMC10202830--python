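"""Readers and writers for the package's tabular and sequence formats.

Sequences travel as multi-record FASTA plus a JSON/YAML manifest keyed by
record id (coiled-coil span, species, role); everything else is CSV/TSV
with the column conventions documented on each function.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .coilscan import ResidueChain
from .mechanofit import BindingSeries, ForceCurve
from .morphometry import JunctionTrace, LinescanProfile, PunctaTrain

__all__ = [
    "read_chains",
    "write_chains",
    "read_force_curves",
    "write_force_curves",
    "read_binding_series",
    "write_binding_series",
    "read_traces",
    "read_linescans",
    "write_linescans",
    "read_puncta",
    "write_puncta",
]


def _load_manifest(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def read_chains(fasta: str | Path, manifest: str | Path) -> list[ResidueChain]:
    """Load rod-domain chains from FASTA plus a per-record manifest.

    The manifest maps record id to ``{"cc_span": [start, end],
    "species": ..., "role": ...}`` (1-based inclusive span).
    """
    meta = _load_manifest(manifest)
    chains = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id not in meta:
            continue
        m = meta[rec.id]
        chains.append(
            ResidueChain(
                id=rec.id,
                sequence=str(rec.seq),
                cc_span=tuple(m["cc_span"]),
                species=m.get("species", ""),
                role=m.get("role", ""),
            )
        )
    if not chains:
        raise ValueError(f"no FASTA records matched the manifest ids in {fasta}")
    return chains


def write_chains(
    chains: list[ResidueChain], fasta: str | Path, manifest: str | Path
) -> None:
    with open(fasta, "w") as fh:
        for c in chains:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), 60):
                fh.write(c.sequence[i : i + 60] + "\n")
    meta = {
        c.id: {"cc_span": list(c.cc_span), "species": c.species, "role": c.role}
        for c in chains
    }
    Path(manifest).write_text(json.dumps(meta, indent=1))


def read_force_curves(path: str | Path, **curve_kwargs) -> list[ForceCurve]:
    """Long-format CSV with columns curve_id, indentation_um, force_nN."""
    df = pd.read_csv(path)
    curves = []
    for cid, grp in df.groupby("curve_id", sort=False):
        curves.append(
            ForceCurve(
                indentation=grp["indentation_um"].to_numpy(),
                force=grp["force_nN"].to_numpy(),
                condition=str(grp["condition"].iloc[0]) if "condition" in grp else "",
                **curve_kwargs,
            )
        )
    return curves


def write_force_curves(curves: list[ForceCurve], path: str | Path) -> None:
    frames = []
    for k, c in enumerate(curves):
        frames.append(
            pd.DataFrame(
                {
                    "curve_id": k,
                    "indentation_um": c.indentation,
                    "force_nN": c.force,
                    "condition": c.condition,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False)


def read_binding_series(
    path: str | Path, target_conc: float, label: str = ""
) -> BindingSeries:
    """CSV with columns ligand_nM, response."""
    df = pd.read_csv(path)
    return BindingSeries(
        ligand_conc=df["ligand_nM"].to_numpy(),
        response=df["response"].to_numpy(),
        target_conc=target_conc,
        label=label or Path(path).stem,
    )


def write_binding_series(series: BindingSeries, path: str | Path) -> None:
    pd.DataFrame(
        {"ligand_nM": series.ligand_conc, "response": series.response}
    ).to_csv(path, index=False)


def read_traces(path: str | Path) -> dict[str, JunctionTrace]:
    """CSV with columns trace_id, x_um, y_um (points ordered within a trace)."""
    df = pd.read_csv(path)
    return {
        str(tid): JunctionTrace(points=grp[["x_um", "y_um"]].to_numpy())
        for tid, grp in df.groupby("trace_id", sort=False)
    }


def read_linescans(path: str | Path) -> list[LinescanProfile]:
    """CSV with profile_id, position_nm and one column per channel."""
    df = pd.read_csv(path)
    channels = [c for c in df.columns if c not in ("profile_id", "position_nm")]
    profiles = []
    for _, grp in df.groupby("profile_id", sort=False):
        profiles.append(
            LinescanProfile(
                positions=grp["position_nm"].to_numpy(),
                channels={c: grp[c].to_numpy() for c in channels},
            )
        )
    return profiles


def write_linescans(profiles: list[LinescanProfile], path: str | Path) -> None:
    frames = []
    for k, p in enumerate(profiles):
        d = {"profile_id": k, "position_nm": p.positions}
        d.update(p.channels)
        frames.append(pd.DataFrame(d))
    pd.concat(frames).to_csv(path, index=False)


def read_puncta(path: str | Path) -> dict[str, PunctaTrain]:
    """CSV with junction_id, junction_length_um, start_um, end_um."""
    df = pd.read_csv(path)
    trains = {}
    for jid, grp in df.groupby("junction_id", sort=False):
        trains[str(jid)] = PunctaTrain(
            junction_length=float(grp["junction_length_um"].iloc[0]),
            puncta=list(zip(grp["start_um"], grp["end_um"])),
        )
    return trains


def write_puncta(trains: dict[str, PunctaTrain] | list[PunctaTrain], path: str | Path) -> None:
    if isinstance(trains, list):
        trains = {str(i): t for i, t in enumerate(trains)}
    rows = []
    for jid, t in trains.items():
        for a, b in t.puncta:
            rows.append(
                {
                    "junction_id": jid,
                    "junction_length_um": t.junction_length,
                    "start_um": a,
                    "end_um": b,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
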