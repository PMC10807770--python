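"""Downstream helpers: FDR-based significance calls and tidy score export.

Heavier evaluation layers (survival models, stage tests, TF activity) are
deliberately left to dedicated packages; this module only discretizes scores
by FDR significance and exports long-format tables ready for such tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DIRECTIONS, ScoreResult, bh_fdr

__all__ = [
    "FAMILY_POLICIES",
    "SignificanceCalls",
    "compute_fdr",
    "call_significant",
    "threshold_scores_for_display",
    "to_long_frame",
]

FAMILY_POLICIES = ("per-run", "per-set", "per-sample")


@dataclass
class SignificanceCalls:
    """Boolean n x m significance matrix at FDR < q within a declared family."""

    significant: np.ndarray
    fdr: np.ndarray
    q: float
    family: str
    sample_ids: list[str]
    set_names: list[str]

    @property
    def counts_per_set(self) -> dict[str, int]:
        return {
            name: int(self.significant[:, k].sum()) for k, name in enumerate(self.set_names)
        }

    @property
    def counts_per_sample(self) -> dict[str, int]:
        return {
            sid: int(self.significant[i, :].sum()) for i, sid in enumerate(self.sample_ids)
        }

    @property
    def fraction_significant(self) -> float:
        valid = ~np.isnan(self.fdr)
        return float(self.significant[valid].mean()) if valid.any() else 0.0


def compute_fdr(p_values: np.ndarray, family: str = "per-run") -> np.ndarray:
    """BH-adjust an n x m p-value matrix under a family policy.

    ``per-run`` treats the whole matrix as one family; ``per-set`` adjusts
    each column separately; ``per-sample`` each row.
    """
    p = np.asarray(p_values, dtype=float)
    if family == "per-run":
        return bh_fdr(p)
    if family == "per-set":
        return np.column_stack([bh_fdr(p[:, k]) for k in range(p.shape[1])])
    if family == "per-sample":
        return np.vstack([bh_fdr(p[i, :]) for i in range(p.shape[0])])
    raise ValueError(f"unknown family policy {family!r}; expected one of {FAMILY_POLICIES}")


def call_significant(
    result: ScoreResult,
    q: float,
    family: str = "per-run",
    direction: str = "total",
) -> SignificanceCalls:
    """Call entries significant where family-adjusted FDR is strictly below q.

    Missing p-values (failed gamma fits) yield missing FDR and are never
    called significant.
    """
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    fdr = compute_fdr(result.pvalues(direction), family)
    significant = np.where(np.isnan(fdr), False, fdr < q)
    return SignificanceCalls(
        significant=significant.astype(bool),
        fdr=fdr,
        q=q,
        family=family,
        sample_ids=result.sample_ids,
        set_names=result.set_names,
    )


def threshold_scores_for_display(
    result: ScoreResult,
    q: float,
    family: str = "per-run",
    direction: str = "total",
) -> np.ndarray:
    """Zero out scores whose FDR is >= q; significant scores pass unchanged."""
    if not 0 < q <= 1:
        raise ValueError("q must lie in (0, 1]")
    scores = result.scores(direction)
    fdr = compute_fdr(result.pvalues(direction), family)
    keep = ~np.isnan(fdr) & (fdr < q)
    return np.where(keep, scores, 0.0)


def to_long_frame(
    result: ScoreResult,
    q: float = 0.25,
    family: str = "per-run",
) -> pd.DataFrame:
    """Tidy long-format export across all three directions.

    Columns: sample_id, set_name, direction, score, p, fdr, significant.
    FDR is computed within each direction under the declared family.
    """
    frames = []
    for direction in DIRECTIONS:
        scores = result.scores(direction)
        pvals = result.pvalues(direction)
        fdr = compute_fdr(pvals, family)
        n, m = scores.shape
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(result.sample_ids, m),
                    "set_name": np.tile(result.set_names, n),
                    "direction": direction,
                    "score": scores.ravel(),
                    "p": pvals.ravel(),
                    "fdr": fdr.ravel(),
                    "significant": np.where(np.isnan(fdr.ravel()), False, fdr.ravel() < q),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
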