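"""Contaminant-identification methods operating on ASV count tables.

Four families are implemented:

* :func:`filter_by_negative_control` — remove every ASV present in a
  negative control (binary, dataset-wide).
* :func:`filter_by_abundance` — remove, per sample, every ASV whose
  relative abundance is strictly below a threshold (binary, per-sample).
* :func:`decontam_frequency_scores` / :func:`decontam_classify` — the
  frequency-based classifier: an ASV whose relative frequency varies
  inversely with total DNA concentration is contaminant-like.  For each
  ASV the residual sum of squares of a log-log fit with slope fixed at
  -1 (contaminant model: frequency ∝ 1/concentration) is compared with
  the fit with slope fixed at 0 (non-contaminant model: frequency
  constant); the score is the F-distribution CDF of the ratio, so 0 means
  a perfect contaminant fit and 1 a perfect constant fit.  ASVs scoring
  below a user threshold P* are removed dataset-wide.
* Bayesian source attribution (SourceTracker-style) lives in
  :mod:`contambench.sourcetracker` and is re-exported here.

Every method returns a :class:`RemovalResult`: a retained-fraction matrix
in [0, 1] over (ASV, sample) plus binary keep/remove calls.  The filters
and the frequency classifier are binary (retained fraction 0 or 1); the
source-attribution method is proportional with calls derived by
thresholding at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community_data import (
    AsvTable,
    SampleMetadata,
    ValidationError,
    to_relative_abundance,
)


@dataclass
class RemovalResult:
    """Outcome of one contaminant-removal method.

    ``retained_fraction`` and ``kept`` are DataFrames indexed by ASV with
    one column per (non-control) sample.  ``score`` is an optional
    per-ASV series (method-specific; NaN = not scoreable).
    """

    method_name: str
    params: Mapping[str, object]
    retained_fraction: pd.DataFrame
    kept: pd.DataFrame
    score: pd.Series | None = None

    def __post_init__(self) -> None:
        rf = self.retained_fraction.to_numpy()
        if rf.size and (rf.min() < 0 or rf.max() > 1):
            raise ValidationError("retained_fraction must lie in [0, 1]")
        if not self.retained_fraction.index.equals(self.kept.index) or not (
            self.retained_fraction.columns.equals(self.kept.columns)
        ):
            raise ValidationError("retained_fraction and kept must be aligned")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.retained_fraction.columns)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.retained_fraction.index)

    def call(self, asv_id: str, sample_id: str) -> str:
        return "kept" if bool(self.kept.at[asv_id, sample_id]) else "removed"

    def corrected_table(self, table: AsvTable) -> AsvTable:
        """Counts × retained fraction, rounded toward zero."""
        sub = table.frame[self.sample_ids]
        rf = self.retained_fraction.reindex(index=sub.index, columns=sub.columns)
        if rf.isna().any().any():
            raise ValidationError(
                "removal result does not cover every (asv, sample) of the table"
            )
        corrected = np.floor(sub.to_numpy() * rf.to_numpy()).astype(np.int64)
        return AsvTable(pd.DataFrame(corrected, index=sub.index, columns=sub.columns))

    def to_calls_frame(self, table: AsvTable) -> pd.DataFrame:
        """Long-format calls (asv_id, sample_id, call, retained_fraction,
        score) for every (ASV, sample) pair covered by the result."""
        records = []
        counts = table.frame
        for s in self.sample_ids:
            for a in self.asv_ids:
                records.append(
                    (
                        a,
                        s,
                        int(counts.at[a, s]) if a in counts.index else 0,
                        self.call(a, s),
                        float(self.retained_fraction.at[a, s]),
                        float(self.score.get(a, np.nan)) if self.score is not None else np.nan,
                    )
                )
        return pd.DataFrame(
            records,
            columns=["asv_id", "sample_id", "count", "call", "retained_fraction", "score"],
        )


def _binary_result(
    method_name: str,
    params: Mapping[str, object],
    kept: pd.DataFrame,
    score: pd.Series | None = None,
) -> RemovalResult:
    return RemovalResult(
        method_name=method_name,
        params=dict(params),
        retained_fraction=kept.astype(float),
        kept=kept.astype(bool),
        score=score,
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_by_negative_control(
    table: AsvTable, control_sample_ids: Sequence[str]
) -> RemovalResult:
    """Remove every ASV observed (count > 0) in any listed negative control
    from all non-control samples."""
    missing = [s for s in control_sample_ids if s not in table.sample_ids]
    if missing:
        raise ValidationError(f"unknown control sample identifiers: {missing}")
    if not control_sample_ids:
        raise ValidationError("at least one control sample id is required")
    controls = table.frame[list(control_sample_ids)]
    in_control = (controls > 0).any(axis=1)
    sinks = [s for s in table.sample_ids if s not in set(control_sample_ids)]
    kept = pd.DataFrame(
        np.repeat(~in_control.to_numpy()[:, None], len(sinks), axis=1),
        index=table.asv_ids,
        columns=sinks,
    )
    return _binary_result(
        "negctrl", {"control_sample_ids": list(control_sample_ids)}, kept
    )


def filter_by_abundance(table: AsvTable, threshold: float) -> RemovalResult:
    """Remove, independently in each sample, every ASV whose relative
    abundance is strictly below ``threshold`` (a proportion in (0, 1))."""
    if not (0 < threshold < 1):
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    rel = to_relative_abundance(table)
    kept = rel >= threshold
    return _binary_result("abundance", {"threshold": threshold}, kept)


# ---------------------------------------------------------------------------
# Frequency-based classifier (Decontam-style)
# ---------------------------------------------------------------------------

@dataclass
class FrequencyFit:
    """Per-ASV fit statistics of the frequency classifier.

    ``stats`` has one row per ASV with columns ``n_used``,
    ``ss_contaminant``, ``ss_noncontaminant`` and ``score`` (NaN when
    fewer than ``min_samples`` usable points).  ``sample_ids`` are the
    non-control samples the classifier applies to.
    """

    stats: pd.DataFrame
    sample_ids: list[str]
    min_samples: int

    @property
    def score(self) -> pd.Series:
        return self.stats["score"]


def decontam_frequency_scores(
    table: AsvTable,
    metadata: Sequence[SampleMetadata],
    min_samples: int = 3,
) -> FrequencyFit:
    """Score every ASV by how well its frequency tracks 1/concentration.

    For each ASV, over non-control samples where its frequency is nonzero,
    fit y = log10(frequency) against x = log10(concentration) twice with
    free intercept: slope fixed at -1 (contaminant model) and slope fixed
    at 0 (constant model).  The score is
    ``F.cdf(ss_contaminant / ss_noncontaminant, n-1, n-1)``; low scores
    are contaminant-like.  ASVs with fewer than ``min_samples`` usable
    points get an undefined (NaN) score.
    """
    meta = {m.sample_id: m for m in metadata}
    missing = [s for s in table.sample_ids if s not in meta]
    if missing:
        raise ValidationError(f"samples without metadata: {missing}")
    sinks = [s for s in table.sample_ids if not meta[s].is_control]
    if not sinks:
        raise ValidationError("no non-control samples to fit")
    sub = table.subset_samples(sinks)
    rel = to_relative_abundance(sub).to_numpy()
    conc = np.array([meta[s].dna_concentration for s in sinks])
    for s, c in zip(sinks, conc):
        if c <= 0:
            raise ValidationError(
                f"sample {s!r}: non-positive DNA concentration {c} cannot be used "
                "by the frequency classifier"
            )
    x = np.log10(conc)

    nonzero = rel > 0
    with np.errstate(divide="ignore"):
        y = np.where(nonzero, np.log10(np.where(nonzero, rel, 1.0)), np.nan)

    n_used = nonzero.sum(axis=1)
    # slope -1: residuals of (y + x) about its mean; slope 0: y about its mean
    def _masked_ss(values: np.ndarray) -> np.ndarray:
        v = np.where(nonzero, values, 0.0)
        denom = np.maximum(n_used, 1)
        mean = v.sum(axis=1, keepdims=True) / denom[:, None]
        dev = np.where(nonzero, v - mean, 0.0)
        return (dev**2).sum(axis=1)

    with np.errstate(invalid="ignore"):
        ss_contaminant = _masked_ss(y + x[None, :])
        ss_noncontaminant = _masked_ss(y)

    dof = n_used - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            ss_noncontaminant > 0,
            ss_contaminant / np.where(ss_noncontaminant > 0, ss_noncontaminant, 1.0),
            np.inf,
        )
        ratio = np.where((ss_noncontaminant == 0) & (ss_contaminant == 0), 1.0, ratio)
    score = np.where(
        np.isinf(ratio), 1.0, stats.f.cdf(ratio, np.maximum(dof, 1), np.maximum(dof, 1))
    )
    score = np.where(n_used >= min_samples, score, np.nan)
    frame = pd.DataFrame(
        {
            "n_used": n_used,
            "ss_contaminant": ss_contaminant,
            "ss_noncontaminant": ss_noncontaminant,
            "score": score,
        },
        index=table.asv_ids,
    )
    return FrequencyFit(stats=frame, sample_ids=sinks, min_samples=min_samples)


def decontam_classify(fit: FrequencyFit, p_star: float) -> RemovalResult:
    """Binary dataset-wide classification at threshold P*.

    An ASV is removed from every sample iff its score is strictly below
    ``p_star``; unscoreable ASVs (NaN score) are kept and remain flagged
    via the NaN in ``score``.
    """
    if not (0 < p_star <= 1):
        raise ValidationError(f"p_star must be in (0, 1], got {p_star}")
    score = fit.stats["score"]
    removed = score < p_star  # NaN compares False -> kept
    kept = pd.DataFrame(
        np.repeat((~removed).to_numpy()[:, None], len(fit.sample_ids), axis=1),
        index=score.index,
        columns=fit.sample_ids,
    )
    return _binary_result("frequency", {"p_star": p_star}, kept, score=score.copy())


# Bayesian source attribution (re-exported for a single method surface)
from .sourcetracker import (  # noqa: E402,F401
    SourceAttribution,
    SourceSet,
    build_source_set,
    contaminant_profile_source,
    gibbs_source_attribution,
    sourcetracker_correct,
)
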