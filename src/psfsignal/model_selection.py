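"""Model comparison by approximate leave-one-out cross-validation.

Each fitted model records, for every retained posterior draw, the marginal
log-likelihood of each species pair (latent layers integrated out). Pairs are
the leave-one-out unit: they are the level at which the seven models differ,
while replicates within a pair are pseudoreplicates of the same unit.

PSIS-LOO (Pareto-smoothed importance sampling) estimates each model's
expected log pointwise predictive density (elpd) from those matrices; the
table reports it on the deviance scale, LOO = -2 * elpd, so smaller is
better, together with the gap to the best model (dLOO). A gap larger than 10
is conventionally read as very strong support for the better model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd

from .hier_models import MODEL_SUMMARIES, PosteriorResult

__all__ = ["LooEstimate", "LOOTable", "psis_loo", "compare", "DELTA_LOO_STRONG"]

logger = logging.getLogger(__name__)

#: Conventional threshold above which a LOO difference is very strong support.
DELTA_LOO_STRONG = 10.0


@dataclass(frozen=True)
class LooEstimate:
    """PSIS-LOO estimate for one model."""

    elpd_loo: float
    se: float
    pareto_k: np.ndarray
    n_pairs: int

    @property
    def loo_deviance(self) -> float:
        """LOO on the deviance scale (-2 * elpd), smaller is better."""
        return -2.0 * self.elpd_loo

    @property
    def n_bad_k(self) -> int:
        return int(np.sum(self.pareto_k > 0.7))


class ComparabilityError(ValueError):
    """Models being compared were not fitted to the same species pairs."""


def psis_loo(pointwise_loglik: np.ndarray) -> LooEstimate:
    """PSIS-LOO from a pointwise log-likelihood array.

    ``pointwise_loglik`` is (draws, pairs) or (chains, draws, pairs). Emits a
    reliability warning when more than 10% of pairs have Pareto tail-shape
    k > 0.7, which signals that importance sampling is unstable for those
    pairs and the estimate may be optimistic.
    """
    ll = np.asarray(pointwise_loglik, float)
    if ll.ndim == 2:
        ll = ll[None, :, :]
    if ll.ndim != 3:
        raise ValueError("pointwise_loglik must be (draws, pairs) or (chains, draws, pairs)")
    if not np.all(np.isfinite(ll)):
        raise ValueError("pointwise log-likelihoods must be finite")
    if ll.shape[0] * ll.shape[1] < 100:
        raise ValueError("need at least 100 posterior draws for PSIS-LOO")

    if np.allclose(ll.var(axis=(0, 1)), 0.0):
        # No Monte-Carlo variation: the predictive density is the pointwise
        # likelihood itself and importance weights are uniform.
        point = ll.mean(axis=(0, 1))
        elpd = float(point.sum())
        se = float(np.sqrt(point.size * np.var(point)))
        return LooEstimate(
            elpd_loo=elpd, se=se, pareto_k=np.zeros(point.size), n_pairs=point.size
        )

    # arviz wants a posterior group for the relative-efficiency correction;
    # the total log-likelihood is a sampled scalar with representative mixing
    idata = az.from_dict(
        posterior={"total_loglik": ll.sum(axis=2)},
        log_likelihood={"pair": ll},
    )
    res = az.loo(idata, pointwise=True)
    pareto_k = np.asarray(res.pareto_k)
    est = LooEstimate(
        elpd_loo=float(res.elpd_loo),
        se=float(res.se),
        pareto_k=pareto_k,
        n_pairs=int(pareto_k.size),
    )
    if est.n_bad_k > 0.1 * est.n_pairs:
        logger.warning(
            "PSIS-LOO reliability warning: %d/%d pairs with Pareto k > 0.7",
            est.n_bad_k,
            est.n_pairs,
        )
    return est


@dataclass
class LOOTable:
    """Deviance-scale LOO comparison across models, best first."""

    table: pd.DataFrame
    notes: list[str]

    def __str__(self) -> str:
        lines = [
            self.table.to_string(
                float_format=lambda v: f"{v:.1f}", index=False
            )
        ]
        lines += self.notes
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6g")


def compare(
    results: Sequence[PosteriorResult],
    labels: Sequence[str] | None = None,
) -> LOOTable:
    """Rank fitted models by PSIS-LOO on the deviance scale.

    All results must be fitted to the identical set of species pairs. The
    returned table is sorted ascending by LOO (best model first) with
    dLOO = LOO - min(LOO); a note flags comparisons where dLOO exceeds
    :data:`DELTA_LOO_STRONG`.
    """
    if not results:
        raise ValueError("no results to compare")
    pair_sets = {tuple(r.pair_ids) for r in results}
    if len(pair_sets) != 1:
        raise ComparabilityError("results were fitted to different species-pair sets")
    if labels is None:
        labels = [f"model {r.spec.model_id}" for r in results]

    rows = []
    for result, label in zip(results, labels):
        est = psis_loo(result.pointwise_loglik)
        rows.append(
            {
                "model": result.spec.model_id,
                "label": label,
                "summary": MODEL_SUMMARIES[result.spec.model_id],
                "elpd_loo": est.elpd_loo,
                "elpd_se": est.se,
                "loo": est.loo_deviance,
                "n_pareto_k_gt_0.7": est.n_bad_k,
            }
        )
    frame = pd.DataFrame(rows).sort_values("loo", kind="stable").reset_index(drop=True)
    frame["delta_loo"] = frame["loo"] - frame["loo"].iloc[0]

    notes = []
    strong = frame[frame["delta_loo"] > DELTA_LOO_STRONG]
    if len(strong):
        best = frame.iloc[0]
        notes.append(
            f"dLOO > {DELTA_LOO_STRONG:g} vs best ({best['label']}) for: "
            + ", ".join(strong["label"])
            + " — very strong support for the better model"
        )
    return LOOTable(table=frame, notes=notes)
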