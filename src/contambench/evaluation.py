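"""Scoring of contaminant-removal methods against ground truth.

Given a count table, the expected-ASV reference, and a method's
:class:`~contambench.removal_methods.RemovalResult`, this module
computes:

* per-ASV truth labels (mock vs contaminant, by reference membership);
* percent contaminants per sample (reads not from expected ASVs);
* per-sample confusion counts and accuracy, where a true positive is a
  contaminant ASV that was removed and a true negative a mock ASV that
  was kept (plus a dataset-wide variant, since some methods call ASVs
  once for the whole dataset);
* alpha diversity (observed ASVs, Shannon with natural log, inverse
  Simpson) with "expected" counterparts computed on the expected-ASV
  subset of each sample;
* composition recovery: the L1 distance between the corrected relative
  abundances and the true mock profile.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community_data import AsvTable, ExpectedReference, ValidationError
from .removal_methods import RemovalResult

ALPHA_METRICS = ("observed", "shannon", "inv_simpson")


def label_ground_truth(table: AsvTable, reference: ExpectedReference) -> pd.Series:
    """Label every table ASV ``mock`` (id in the reference) or
    ``contaminant``."""
    return pd.Series(
        ["mock" if a in reference.id_set else "contaminant" for a in table.asv_ids],
        index=table.asv_ids,
        name="label",
    )


def percent_contaminants(table: AsvTable, labels: pd.Series) -> pd.Series:
    """Percentage of each sample's reads carried by contaminant-labeled
    ASVs; NaN for zero-read samples."""
    aligned = labels.reindex(table.asv_ids)
    if aligned.isna().any():
        missing = aligned[aligned.isna()].index.tolist()
        raise ValidationError(f"ASVs without labels: {missing}")
    is_contam = (aligned == "contaminant").to_numpy()
    counts = table.frame.to_numpy()
    totals = counts.sum(axis=0).astype(float)
    contam = counts[is_contam].sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(totals > 0, 100.0 * contam / totals, np.nan)
    return pd.Series(pct, index=table.sample_ids, name="pct_contaminants")


def confusion_and_accuracy(
    result: RemovalResult, labels: pd.Series, table: AsvTable
) -> pd.DataFrame:
    """Per-sample confusion counts over ASVs present (count > 0) in each
    sample covered by the result.

    Columns: tp (contaminants removed), fn (contaminants kept), tn (mock
    kept), fp (mock removed), accuracy, pct_contaminant_correct,
    pct_mock_misclassified.  A sample with no contaminants present and
    nothing removed scores accuracy 1.
    """
    rows = []
    counts = table.frame
    for s in result.sample_ids:
        present = counts.index[counts[s] > 0]
        missing = present.difference(result.kept.index)
        if len(missing):
            raise ValidationError(
                f"sample {s!r}: no call for present ASVs {missing.tolist()[:5]}"
            )
        kept = result.kept.loc[present, s]
        lab = labels.reindex(present)
        if lab.isna().any():
            raise ValidationError(
                f"sample {s!r}: unlabeled ASVs {lab[lab.isna()].index.tolist()[:5]}"
            )
        is_contam = (lab == "contaminant").to_numpy()
        kept_arr = kept.to_numpy()
        tp = int((is_contam & ~kept_arr).sum())
        fn = int((is_contam & kept_arr).sum())
        tn = int((~is_contam & kept_arr).sum())
        fp = int((~is_contam & ~kept_arr).sum())
        denom = tp + fn + tn + fp
        accuracy = (tp + tn) / denom if denom else np.nan
        rows.append(
            {
                "sample_id": s,
                "tp": tp,
                "fn": fn,
                "tn": tn,
                "fp": fp,
                "accuracy": accuracy,
                "pct_contaminant_correct": 100.0 * tp / (tp + fn) if tp + fn else np.nan,
                "pct_mock_misclassified": 100.0 * fp / (tn + fp) if tn + fp else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def dataset_confusion(
    result: RemovalResult, labels: pd.Series, table: AsvTable
) -> pd.Series:
    """Dataset-wide confusion: each ASV present anywhere is counted once,
    called removed iff it was removed in every sample where present."""
    counts = table.frame[result.sample_ids]
    present_any = counts.sum(axis=1) > 0
    asvs = counts.index[present_any]
    removed = []
    for a in asvs:
        samples = counts.columns[counts.loc[a] > 0]
        removed.append(bool((~result.kept.loc[a, samples]).all()))
    removed = np.asarray(removed)
    lab = labels.reindex(asvs)
    is_contam = (lab == "contaminant").to_numpy()
    tp = int((is_contam & removed).sum())
    fn = int((is_contam & ~removed).sum())
    tn = int((~is_contam & ~removed).sum())
    fp = int((~is_contam & removed).sum())
    denom = tp + fn + tn + fp
    return pd.Series(
        {
            "tp": tp,
            "fn": fn,
            "tn": tn,
            "fp": fp,
            "accuracy": (tp + tn) / denom if denom else np.nan,
        }
    )


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(
    counts: np.ndarray | Sequence[float], metric: str, shannon_base: float | None = None
) -> float:
    """Alpha diversity of one count vector.

    ``observed``: number of nonzero taxa; ``shannon``: -Σ p ln p (natural
    log by default; pass ``shannon_base=2`` for bits); ``inv_simpson``:
    1 / Σ p².
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValidationError("counts must be non-negative")
    total = c.sum()
    if total == 0:
        raise ValidationError("alpha diversity undefined for an all-zero vector")
    if metric == "observed":
        return float((c > 0).sum())
    p = c[c > 0] / total
    if metric == "shannon":
        h = float(-(p * np.log(p)).sum())
        return h / math.log(shannon_base) if shannon_base else h
    if metric == "inv_simpson":
        return float(1.0 / (p**2).sum())
    raise ValidationError(f"unknown metric {metric!r}; choose from {ALPHA_METRICS}")


def alpha_diversity_table(table: AsvTable, metrics: Sequence[str] = ALPHA_METRICS) -> pd.DataFrame:
    """Alpha diversity per sample (rows = samples, columns = metrics);
    NaN for zero-read samples."""
    rows = {}
    for s in table.sample_ids:
        c = table.column(s)
        rows[s] = {
            m: (alpha_diversity(c, m) if c.sum() > 0 else np.nan) for m in metrics
        }
    return pd.DataFrame.from_dict(rows, orient="index")[list(metrics)]


def expected_alpha(
    table: AsvTable, reference: ExpectedReference, metric: str
) -> pd.Series:
    """Alpha diversity of each sample restricted to the expected ASVs
    (the contaminant-free counterpart); NaN where a sample carries no
    expected reads."""
    mask = table.frame.index.isin(reference.id_set)
    sub = table.frame.loc[mask]
    values = {}
    for s in table.sample_ids:
        c = sub[s].to_numpy()
        values[s] = alpha_diversity(c, metric) if c.sum() > 0 else np.nan
    return pd.Series(values, name=f"expected_{metric}")


# ---------------------------------------------------------------------------
# Composition recovery
# ---------------------------------------------------------------------------

def composition_recovery(
    corrected: AsvTable,
    truth_profile: pd.Series,
    labels: pd.Series,
) -> pd.DataFrame:
    """Compare corrected relative abundances with the true mock profile.

    ``truth_profile`` is the true relative-abundance vector over expected
    ASVs (summing to 1).  Per sample, the corrected counts are converted
    to proportions over all retained ASVs; the L1 error is
    Σ_expected |observed − truth| + Σ_contaminant observed  ∈ [0, 2].
    Returns one row per sample: the observed share of each expected ASV,
    the residual contaminant share, and ``l1_error``.
    """
    if abs(truth_profile.sum() - 1.0) > 1e-9:
        raise ValidationError("truth profile must sum to 1")
    sums = corrected.sample_sums()
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(
            f"corrected sample {zero.index[0]!r} has zero reads; "
            "composition recovery undefined"
        )
    rel = corrected.frame / sums
    expected_ids = list(truth_profile.index)
    rows = []
    for s in corrected.sample_ids:
        obs = rel[s]
        obs_expected = obs.reindex(expected_ids).fillna(0.0)
        contam_share = float(obs[~obs.index.isin(expected_ids)].sum())
        l1 = float((obs_expected - truth_profile).abs().sum()) + contam_share
        row = {"sample_id": s, "contaminant_share": contam_share, "l1_error": l1}
        row.update({f"share_{a}": float(obs_expected[a]) for a in expected_ids})
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


def sample_summary(table: AsvTable, labels: pd.Series) -> pd.DataFrame:
    """Reads, unique ASVs and percent contaminants per sample (the
    dilution-series overview table)."""
    reads = table.sample_sums()
    unique = (table.frame > 0).sum(axis=0)
    pct = percent_contaminants(table, labels)
    return pd.DataFrame(
        {"n_reads": reads, "n_unique_asvs": unique, "pct_contaminants": pct}
    )
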