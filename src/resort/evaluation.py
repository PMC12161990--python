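"""Evaluation metrics: per-spot agreement, infiltration calling, stratification.

Per-spot Pearson correlation measures the linear alignment between the
estimated and true proportion vectors of each spot; per-spot KL divergence
(relative entropy of truth against estimate, with a pseudo-count to stay
finite) measures their distributional divergence.  Immune infiltration is
evaluated as a two-class problem over tumour spots — infiltrated vs pure —
scored by per-class precision/recall/F1 and a class-size-weighted F1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr
from sklearn.metrics import f1_score, precision_recall_fscore_support

from .types import ProportionMatrix, RegionAssignment, ValidationError

logger = logging.getLogger("resort")

KL_PSEUDO = 1e-9


def _check_aligned(p_true: ProportionMatrix, p_est: ProportionMatrix) -> None:
    if p_true.type_ids != p_est.type_ids:
        raise ValidationError(
            f"type sets differ: {p_true.type_ids} vs {p_est.type_ids}"
        )
    if p_true.spot_ids != p_est.spot_ids:
        raise ValidationError("spot sets differ between truth and estimate")


def pearson_per_spot(
    p_true: ProportionMatrix, p_est: ProportionMatrix
) -> np.ndarray:
    """Pearson ρ of the two proportion vectors, per spot.

    Spots where either vector is constant have undefined ρ and are returned
    as NaN (excluded from any mean, with a logged count) rather than zero.
    """
    _check_aligned(p_true, p_est)
    if len(p_true.type_ids) < 2:
        raise ValidationError("need at least two types for a per-spot correlation")
    a = p_true.values - p_true.values.mean(axis=1, keepdims=True)
    b = p_est.values - p_est.values.mean(axis=1, keepdims=True)
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na > 0) & (nb > 0)
    rho = np.full(p_true.n_spots, np.nan)
    rho[ok] = np.clip(
        np.einsum("ij,ij->i", a[ok], b[ok]) / (na[ok] * nb[ok]), -1.0, 1.0
    )
    n_missing = int((~ok).sum())
    if n_missing:
        logger.info(
            "%d spots had a constant proportion vector; their correlation is "
            "undefined and excluded",
            n_missing,
        )
    return rho


def kl_per_spot(
    p_true: ProportionMatrix,
    p_est: ProportionMatrix,
    pseudo: float = KL_PSEUDO,
) -> np.ndarray:
    """KL(truth ‖ estimate) per spot, in nats.

    Both rows receive an additive pseudo-count and are renormalised before
    the divergence is taken, keeping the result finite when the estimate has
    exact zeros where the truth does not.
    """
    _check_aligned(p_true, p_est)
    if pseudo < 0:
        raise ValidationError("pseudo-count must be >= 0")
    p = p_true.values + pseudo
    q = p_est.values + pseudo
    p = p / p.sum(axis=1, keepdims=True)
    q = q / q.sum(axis=1, keepdims=True)
    return rel_entr(p, q).sum(axis=1)


def summarize_metrics(rho: np.ndarray, kl: np.ndarray) -> dict[str, float]:
    """Mean/median summaries, ignoring undefined correlations."""
    return {
        "pearson_mean": float(np.nanmean(rho)),
        "pearson_median": float(np.nanmedian(rho)),
        "kl_mean": float(np.mean(kl)),
        "kl_median": float(np.median(kl)),
        "n_spots": int(rho.size),
        "n_undefined_pearson": int(np.isnan(rho).sum()),
    }


@dataclass
class InfiltrationReport:
    """Two-class scoring of infiltrated vs pure tumour spots."""

    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    weighted_f1: float
    threshold: float

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "support": self.support,
            "weighted_f1": self.weighted_f1,
            "threshold": self.threshold,
        }


def classify_infiltration(
    p_est: ProportionMatrix,
    immune_type: str,
    threshold: float,
    truth_mask: np.ndarray,
    cancer_mask: np.ndarray,
) -> InfiltrationReport:
    """Call tumour spots infiltrated when the estimated immune share ≥ threshold.

    Only spots inside ``cancer_mask`` are scored.  Per-class precision,
    recall and F1 are computed for the infiltrated and pure classes, plus an
    F1 weighted by the class sizes in the truth.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError("threshold must lie in [0, 1]")
    truth_mask = np.asarray(truth_mask, dtype=bool)
    cancer_mask = np.asarray(cancer_mask, dtype=bool)
    if truth_mask.shape != (p_est.n_spots,) or cancer_mask.shape != (p_est.n_spots,):
        raise ValidationError("masks must align with the estimate's spots")
    if not cancer_mask.any():
        raise ValidationError("cancer mask selects no spots")
    immune = p_est.column(immune_type)
    y_true = truth_mask[cancer_mask]
    y_pred = immune[cancer_mask] >= threshold
    labels = [True, False]  # infiltrated, pure
    prec, rec, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, zero_division=0
    )
    weighted = float(
        f1_score(y_true, y_pred, labels=labels, average="weighted", zero_division=0)
    )
    names = ["infiltrated", "pure"]
    return InfiltrationReport(
        precision=dict(zip(names, map(float, prec))),
        recall=dict(zip(names, map(float, rec))),
        f1=dict(zip(names, map(float, f1))),
        support=dict(zip(names, map(int, support))),
        weighted_f1=weighted,
        threshold=float(threshold),
    )


_KNOWN_RULES = {"pure_threshold", "mixture_threshold", "split"}


def stratify_spots(
    p_est: ProportionMatrix, rules: dict | None = None
) -> np.ndarray:
    """Categorise spots as pure, two-type mixtures, or other.

    A spot is ``pure-<type>`` when its top proportion reaches
    ``pure_threshold`` (default 0.9); otherwise, when its top two types both
    reach ``mixture_threshold`` (default 0.1), it is an ``<X>-<Y> mixture``
    (named in type order); anything else is ``other``.  An optional
    ``split`` rule relabels one mixture category by spatial membership:
    ``{"category": ..., "inside_spots": set of spot ids}`` marks members
    inside the named region's spot set as ``infiltrated`` and the rest as
    ``peripheral``.
    """
    rules = dict(rules or {})
    unknown = sorted(set(rules) - _KNOWN_RULES)
    if unknown:
        raise ValidationError(
            f"unknown stratification rules {unknown}; known: {sorted(_KNOWN_RULES)}"
        )
    pure_t = float(rules.get("pure_threshold", 0.9))
    mix_t = float(rules.get("mixture_threshold", 0.1))

    cats = np.empty(p_est.n_spots, dtype=object)
    for s in range(p_est.n_spots):
        row = p_est.values[s]
        order = np.argsort(row)[::-1]
        if row[order[0]] >= pure_t:
            cats[s] = f"pure-{p_est.type_ids[order[0]]}"
        elif len(row) >= 2 and row[order[1]] >= mix_t:
            i, j = sorted(order[:2])
            cats[s] = f"{p_est.type_ids[i]}-{p_est.type_ids[j]} mixture"
        else:
            cats[s] = "other"

    if "split" in rules:
        split = rules["split"]
        extra = sorted(set(split) - {"category", "inside_spots"})
        if extra:
            raise ValidationError(f"unknown split rule keys {extra}")
        category = str(split["category"])
        inside = {str(x) for x in split["inside_spots"]}
        for s, sid in enumerate(p_est.spot_ids):
            if cats[s] == category:
                cats[s] = "infiltrated" if sid in inside else "peripheral"
    return cats


def split_mixture_by_region(
    categories: np.ndarray,
    spot_ids: list[str],
    mixture_category: str,
    assignment: RegionAssignment,
    region_id: str,
) -> np.ndarray:
    """Relabel one mixture category by a detected region's boundary.

    Members of ``mixture_category`` lying inside region ``region_id`` become
    ``infiltrated``; the remaining members become ``peripheral``.
    """
    inside = {
        sid
        for sid, lab in zip(assignment.spot_ids, assignment.labels)
        if lab == str(region_id)
    }
    out = np.asarray(categories, dtype=object).copy()
    for s, sid in enumerate(spot_ids):
        if out[s] == mixture_category:
            out[s] = "infiltrated" if sid in inside else "peripheral"
    return out
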