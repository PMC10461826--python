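"""Sample-overlap correlation between case-control studies.

Two GWAS drawn from the same cohort share cases and controls, which
induces correlation between their effect estimates even at null SNPs.
Following Lin and Sullivan, for studies k and l with n_k0/n_k1 controls
and cases in study k, n_l0/n_l1 in study l, and n0/n1 shared controls and
cases, the expected correlation is

    rho = [ n0 sqrt( (n_k1 n_l1) / (n_k0 n_l0) )
          + n1 sqrt( (n_k0 n_l0) / (n_k1 n_l1) ) ]
          / sqrt( (n_k0 + n_k1) (n_l0 + n_l1) ).

The subscript order "n_k0 = controls of study k" is fixed here as the one
canonical convention. rho lies in [0, 1]: 0 with no overlap, 1 for a
study paired with itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputValidationError

DESIGN_COLUMNS = (
    "study_k", "study_l", "n0_shared_controls", "n1_shared_cases",
    "k_controls", "k_cases", "l_controls", "l_cases",
)


@dataclass
class OverlapDesign:
    """Case/control totals and shared counts for one pair of studies."""

    study_k: str
    study_l: str
    n0: int  #: shared controls
    n1: int  #: shared cases
    n_k0: int  #: controls in study k
    n_k1: int  #: cases in study k
    n_l0: int  #: controls in study l
    n_l1: int  #: cases in study l

    def __post_init__(self) -> None:
        for name in ("n_k0", "n_k1", "n_l0", "n_l1"):
            if getattr(self, name) <= 0:
                raise InputValidationError(
                    f"{name} must be positive, got {getattr(self, name)}"
                )
        if not 0 <= self.n0 <= min(self.n_k0, self.n_l0):
            raise InputValidationError(
                f"shared controls n0={self.n0} outside "
                f"[0, min(n_k0, n_l0)={min(self.n_k0, self.n_l0)}]"
            )
        if not 0 <= self.n1 <= min(self.n_k1, self.n_l1):
            raise InputValidationError(
                f"shared cases n1={self.n1} outside "
                f"[0, min(n_k1, n_l1)={min(self.n_k1, self.n_l1)}]"
            )


def rho_overlap(design: OverlapDesign) -> float:
    """Expected effect-estimate correlation at null SNPs for one pair."""
    d = design
    ratio = (d.n_k1 * d.n_l1) / (d.n_k0 * d.n_l0)
    num = d.n0 * math.sqrt(ratio) + d.n1 * math.sqrt(1.0 / ratio)
    den = math.sqrt((d.n_k0 + d.n_k1) * (d.n_l0 + d.n_l1))
    return num / den


def read_design_table(path) -> pd.DataFrame:
    """Read a TSV of overlap designs (schema: ``DESIGN_COLUMNS``)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in DESIGN_COLUMNS if c not in df.columns]
    if missing:
        raise InputValidationError(
            f"design table is missing column(s): {', '.join(missing)}"
        )
    return df


def _designs_from_table(table: pd.DataFrame) -> list[OverlapDesign]:
    return [
        OverlapDesign(
            study_k=str(r.study_k), study_l=str(r.study_l),
            n0=int(r.n0_shared_controls), n1=int(r.n1_shared_cases),
            n_k0=int(r.k_controls), n_k1=int(r.k_cases),
            n_l0=int(r.l_controls), n_l1=int(r.l_cases),
        )
        for r in table.itertuples(index=False)
    ]


def pairwise_rho(table: pd.DataFrame):
    """rho for every study pair in a design table.

    Each unordered pair may appear at most once. Returns
    ``(matrix, summary, long)``: a symmetric DataFrame with unit diagonal,
    summary statistics (min / median / max over off-diagonal entries), and
    the per-pair long-format table ready to write as TSV.
    """
    designs = _designs_from_table(table)
    seen = set()
    for d in designs:
        key = frozenset((d.study_k, d.study_l))
        if key in seen:
            raise InputValidationError(
                f"duplicate study pair: {d.study_k} / {d.study_l}"
            )
        seen.add(key)
    studies = list(dict.fromkeys(
        [d.study_k for d in designs] + [d.study_l for d in designs]
    ))
    mat = pd.DataFrame(np.eye(len(studies)), index=studies, columns=studies)
    rows = []
    for d in designs:
        r = rho_overlap(d)
        mat.loc[d.study_k, d.study_l] = r
        mat.loc[d.study_l, d.study_k] = r
        rows.append({"study_k": d.study_k, "study_l": d.study_l, "rho": r})
    long = pd.DataFrame(rows)
    vals = long["rho"].to_numpy()
    summary = {
        "min": float(np.min(vals)),
        "median": float(np.median(vals)),
        "max": float(np.max(vals)),
        "n_pairs": int(vals.size),
    }
    return mat, summary, long
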