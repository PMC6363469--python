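"""Plain-text interchange formats.

Per-participant pattern data is laid out as one directory per participant
containing, per run and ROI, a delimited conditions-by-voxels beta matrix
and a timepoints-by-voxels residual matrix, each with a JSON sidecar
(condition labels, ROI, hand, degrees of freedom, seed).  RDMs and summary
measures travel as long-format CSV tables readable by the stats module.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from limbrsa.rdm import RDM, pair_labels
from limbrsa.synthetic import RunPatterns

__all__ = [
    "write_participant",
    "read_participant",
    "rdm_long_table",
    "rdms_from_long_table",
]


def write_participant(out_dir: str | Path, participant: str, patterns: dict) -> Path:
    """Write ``roi -> list[RunPatterns]`` for one participant."""
    pdir = Path(out_dir) / participant
    pdir.mkdir(parents=True, exist_ok=True)
    for roi, runs in patterns.items():
        for rp in runs:
            stem = f"{roi}_run-{rp.run:02d}"
            np.savetxt(pdir / f"{stem}_betas.tsv", rp.betas, delimiter="\t")
            np.savetxt(pdir / f"{stem}_residuals.tsv", rp.residuals, delimiter="\t")
            sidecar = {
                "participant": rp.participant or participant,
                "group": rp.group,
                "roi": roi,
                "hand": rp.hand,
                "run": rp.run,
                "conditions": list(rp.conditions),
                "dof": rp.dof,
            }
            (pdir / f"{stem}.json").write_text(json.dumps(sidecar, indent=1))
    return pdir


def read_participant(pdir: str | Path) -> dict:
    """Read back a participant directory into ``roi -> list[RunPatterns]``."""
    pdir = Path(pdir)
    patterns: dict[str, list[RunPatterns]] = {}
    for sidecar_path in sorted(pdir.glob("*_run-*.json")):
        meta = json.loads(sidecar_path.read_text())
        stem = sidecar_path.stem
        betas = np.loadtxt(pdir / f"{stem}_betas.tsv", delimiter="\t", ndmin=2)
        residuals = np.loadtxt(pdir / f"{stem}_residuals.tsv", delimiter="\t", ndmin=2)
        rp = RunPatterns(
            betas=betas,
            residuals=residuals,
            dof=int(meta["dof"]),
            conditions=tuple(meta["conditions"]),
            roi=meta["roi"],
            run=int(meta["run"]),
            participant=meta["participant"],
            group=meta.get("group", ""),
            hand=meta.get("hand", ""),
        )
        patterns.setdefault(meta["roi"], []).append(rp)
    for runs in patterns.values():
        runs.sort(key=lambda rp: rp.run)
    return patterns


def rdm_long_table(rdms: list[RDM]) -> pd.DataFrame:
    """Long-format table (participant, group, roi, hand, pair, distance)."""
    rows = []
    for rdm in rdms:
        labels = pair_labels(rdm.conditions)
        meta = rdm.meta
        for pair, dist in zip(labels, rdm.vector):
            rows.append(
                {
                    "participant": meta.get("participant", ""),
                    "group": meta.get("group", ""),
                    "roi": meta.get("roi", ""),
                    "hand": meta.get("hand", ""),
                    "pair": pair,
                    "distance": dist,
                }
            )
    return pd.DataFrame(rows)


def rdms_from_long_table(table: pd.DataFrame, conditions=("D1", "D2", "D3", "D4", "D5")) -> list[RDM]:
    """Rebuild RDM objects from a long-format table."""
    labels = pair_labels(conditions)
    out = []
    for (participant, roi), grp in table.groupby(["participant", "roi"], sort=True):
        vec = grp.set_index("pair").loc[labels, "distance"].to_numpy()
        meta = {
            "participant": participant,
            "roi": roi,
            "group": grp["group"].iloc[0],
            "hand": grp["hand"].iloc[0],
        }
        out.append(RDM.from_vector(vec, conditions=conditions, meta=meta))
    return out
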