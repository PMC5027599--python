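"""Localization-set evaluation against a ground-truth reference.

A reconstructed localization counts as a true positive when it can be
paired one-to-one with a reference localization within a tolerance radius
(conventionally the PSF FWHM).  The pairing is an optimal assignment on the
within-tolerance pair graph: maximum number of pairs first, minimum total
distance among maximum matchings.  From the pairing:

    TP = matched pairs          Jaccard   = TP / (TP + FP + FN)
    FP = reconstructed - TP     Precision = TP / (TP + FP)
    FN = reference - TP         Recall    = TP / (TP + FN)

and RMSD is the root-mean-square pair distance over matched pairs only.
Matching is per frame by default: localizations in different frames never
pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

__all__ = ["MatchReport", "match_localizations", "fwhm_tolerance_nm"]


def fwhm_tolerance_nm(s0_px: float, pixel_size_sample_nm: float) -> float:
    """Default matching tolerance: the PSF full width at half maximum in nm."""
    return 2.0 * np.sqrt(2.0 * np.log(2.0)) * s0_px * pixel_size_sample_nm


def _ratio(a: int, b: int) -> float:
    return a / b if b else 0.0


@dataclass(frozen=True)
class MatchReport:
    """Matching outcome and derived quality metrics."""

    tp: int
    fp: int
    fn: int
    rmsd_nm: float
    tolerance_nm: float
    pairs: list = field(default_factory=list)  # (ref index, recon index, distance nm)

    @property
    def jaccard(self) -> float:
        return _ratio(self.tp, self.tp + self.fp + self.fn)

    @property
    def precision(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def recall(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "fp": self.fp, "fn": self.fn,
                "jaccard": self.jaccard, "precision": self.precision,
                "recall": self.recall, "rmsd_nm": self.rmsd_nm,
                "tolerance_nm": self.tolerance_nm}


def _as_table(t) -> pd.DataFrame:
    if isinstance(t, pd.DataFrame):
        df = t
    else:
        df = pd.DataFrame(t)
    missing = {"x_nm", "y_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"localization table is missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(df[["x_nm", "y_nm"]].to_numpy(dtype=float))):
        raise ValueError("localization table contains non-finite coordinates")
    return df


def _match_block(ref_xy: np.ndarray, rec_xy: np.ndarray, tol: float):
    """Optimal pairing of one frame: max cardinality, then min total distance."""
    if len(ref_xy) == 0 or len(rec_xy) == 0:
        return []
    d = cdist(ref_xy, rec_xy)
    feasible = d <= tol
    if not feasible.any():
        return []
    # a large constant on infeasible edges makes the assignment prefer any
    # set of feasible pairs over fewer (max cardinality), then the real
    # distances break ties (min total distance)
    big = tol * (d.shape[0] + d.shape[1] + 1) * 1e3 + d[feasible].sum()
    cost = np.where(feasible, d, big)
    rows, cols = linear_sum_assignment(cost)
    return [(int(r), int(c), float(d[r, c])) for r, c in zip(rows, cols) if feasible[r, c]]


def match_localizations(reference, reconstructed, tolerance_nm: float,
                        per_frame: bool = True) -> MatchReport:
    """Match a reconstructed localization table against a reference table.

    Both tables need columns ``x_nm, y_nm`` (and ``frame`` when
    ``per_frame``).  Returns a :class:`MatchReport`; pair indices refer to
    table row order.
    """
    ref = _as_table(reference)
    rec = _as_table(reconstructed)
    if per_frame:
        for name, df in (("reference", ref), ("reconstructed", rec)):
            if "frame" not in df.columns:
                raise ValueError(f"{name} table needs a 'frame' column for per-frame matching")

    pairs: list[tuple[int, int, float]] = []
    if per_frame:
        ref_groups = {k: v for k, v in ref.groupby("frame").indices.items()}
        rec_groups = {k: v for k, v in rec.groupby("frame").indices.items()}
        for fr, ridx in ref_groups.items():
            cidx = rec_groups.get(fr)
            if cidx is None:
                continue
            sub = _match_block(ref.iloc[ridx][["x_nm", "y_nm"]].to_numpy(float),
                               rec.iloc[cidx][["x_nm", "y_nm"]].to_numpy(float),
                               tolerance_nm)
            pairs.extend((int(ridx[r]), int(cidx[c]), dnm) for r, c, dnm in sub)
    else:
        pairs = _match_block(ref[["x_nm", "y_nm"]].to_numpy(float),
                             rec[["x_nm", "y_nm"]].to_numpy(float), tolerance_nm)

    tp = len(pairs)
    fp = len(rec) - tp
    fn = len(ref) - tp
    rmsd = float(np.sqrt(np.mean([d * d for _, _, d in pairs]))) if pairs else 0.0
    return MatchReport(tp=tp, fp=fp, fn=fn, rmsd_nm=rmsd,
                       tolerance_nm=float(tolerance_nm), pairs=pairs)
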