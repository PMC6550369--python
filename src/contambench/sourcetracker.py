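"""Bayesian microbial source tracking by collapsed Gibbs sampling.

Each read of a *sink* sample is attributed to one of several *source*
environments (fixed count profiles supplied by the user) or, optionally,
to an *unknown* source whose composition is learned on the fly.  The
model is the standard one for community source tracking: source mixing
proportions carry a symmetric Dirichlet(β) prior, each known source v
emits taxon t with fixed probability

    P(t | v) = (m_tv + α_known) / (m_v + α_known · τ)

(m: source counts, τ: size of the shared taxon universe), and the
unknown source is a Dirichlet(α_unknown)-smoothed urn over the reads
currently assigned to it.  The collapsed Gibbs update for read i with
taxon t is

    P(z_i = v | z_-i) ∝ P(t | v) · (n_v^(-i) + β)

(the normalizing N - 1 + β·V term is constant across v).  Mixing
proportions are posterior means of n_v / N over retained draws and
restarts; per-taxon attributions are posterior mean fractions of each
taxon's reads assigned to each source.

The sweep kernel is compiled with numba; the package's test suite checks
it against exhaustive enumeration over all assignment vectors on small
sinks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numba import njit

from .community_data import AsvTable, ExpectedReference, ValidationError

UNKNOWN = "unknown"

DEFAULT_HYPERPARAMS: dict[str, float | int] = {
    "alpha_known": 0.001,
    "alpha_unknown": 0.1,
    "beta": 10.0,
    "n_restarts": 10,
    "n_burnin": 100,
    "n_draws": 10,
    "draw_spacing": 10,
    "rarefaction_depth": 0,  # 0 = off
}


@dataclass(frozen=True)
class SourceSet:
    """Named source environments over a shared ASV universe.

    ``profiles`` maps source name → count vector aligned to
    ``asv_ids``.  When ``include_unknown`` is true an extra "unknown"
    source with learned composition is appended during attribution.
    """

    asv_ids: tuple[str, ...]
    profiles: Mapping[str, np.ndarray]
    include_unknown: bool = True

    def __post_init__(self) -> None:
        if not self.profiles:
            raise ValidationError("at least one source is required")
        if UNKNOWN in self.profiles:
            raise ValidationError(f"{UNKNOWN!r} is a reserved source name")
        for name, counts in self.profiles.items():
            counts = np.asarray(counts)
            if counts.shape != (len(self.asv_ids),):
                raise ValidationError(
                    f"source {name!r}: profile length {counts.shape} does not "
                    f"match universe size {len(self.asv_ids)}"
                )
            if np.any(counts < 0):
                raise ValidationError(f"source {name!r}: negative counts")

    @property
    def source_names(self) -> list[str]:
        return list(self.profiles)


@dataclass
class SourceAttribution:
    """Posterior attribution of one sink sample.

    ``mixing`` is the posterior mean mixing proportion per source
    (summing to 1); ``asv_fractions`` has one row per taxon with nonzero
    (post-rarefaction) sink count and one column per source, each row
    summing to 1.
    """

    sink_id: str
    mixing: pd.Series
    asv_fractions: pd.DataFrame
    diagnostics: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if abs(self.mixing.sum() - 1.0) > 1e-9:
            raise ValidationError("mixing proportions must sum to 1")
        if len(self.asv_fractions):
            sums = self.asv_fractions.sum(axis=1)
            if (sums - 1.0).abs().max() > 1e-9:
                raise ValidationError("per-ASV attributed fractions must sum to 1")


@njit(cache=False)
def _gibbs_kernel(
    taxa,  # int64[N] read-level taxon indices
    phi,  # float64[V_known, tau] fixed emission probabilities
    tau,
    alpha_unknown,
    beta,
    include_unknown,
    n_restarts,
    n_burnin,
    n_draws,
    draw_spacing,
    seed,
):
    n_reads = taxa.shape[0]
    n_known = phi.shape[0]
    n_sources = n_known + (1 if include_unknown else 0)
    env_sum = np.zeros(n_sources)
    taxon_source = np.zeros((tau, n_sources))
    probs = np.empty(n_sources)
    total_draws = 0
    for restart in range(n_restarts):
        np.random.seed(seed + restart)
        z = np.empty(n_reads, dtype=np.int64)
        n_v = np.zeros(n_sources)
        q_t = np.zeros(tau)
        q_total = 0.0
        for i in range(n_reads):
            v = np.random.randint(0, n_sources)
            z[i] = v
            n_v[v] += 1
            if include_unknown and v == n_sources - 1:
                q_t[taxa[i]] += 1
                q_total += 1
        n_sweeps = n_burnin + n_draws * draw_spacing
        for sweep in range(n_sweeps):
            for i in range(n_reads):
                t = taxa[i]
                v_old = z[i]
                n_v[v_old] -= 1
                if include_unknown and v_old == n_sources - 1:
                    q_t[t] -= 1
                    q_total -= 1
                total = 0.0
                for v in range(n_known):
                    p = phi[v, t] * (n_v[v] + beta)
                    probs[v] = p
                    total += p
                if include_unknown:
                    p = (
                        (q_t[t] + alpha_unknown)
                        / (q_total + alpha_unknown * tau)
                        * (n_v[n_sources - 1] + beta)
                    )
                    probs[n_sources - 1] = p
                    total += p
                u = np.random.random() * total
                acc = 0.0
                v_new = n_sources - 1
                for v in range(n_sources):
                    acc += probs[v]
                    if u < acc:
                        v_new = v
                        break
                z[i] = v_new
                n_v[v_new] += 1
                if include_unknown and v_new == n_sources - 1:
                    q_t[t] += 1
                    q_total += 1
            if sweep >= n_burnin and (sweep - n_burnin) % draw_spacing == draw_spacing - 1:
                total_draws += 1
                for v in range(n_sources):
                    env_sum[v] += n_v[v] / n_reads
                for i in range(n_reads):
                    taxon_source[taxa[i], z[i]] += 1.0
    return env_sum, taxon_source, total_draws


def gibbs_source_attribution(
    sink: np.ndarray | pd.Series,
    sources: SourceSet,
    hyperparams: Mapping[str, float | int] | None = None,
    rng: np.random.Generator | int | None = None,
    sink_id: str = "sink",
) -> SourceAttribution:
    """Attribute each read of ``sink`` to the sources (plus unknown).

    ``sink`` is a count vector aligned to ``sources.asv_ids``.  With
    ``rarefaction_depth > 0`` the sink is subsampled without replacement
    to that depth first.  Randomness comes from ``rng`` (a Generator, an
    integer seed, or None for seed 0); results are deterministic for a
    fixed seed.
    """
    params = dict(DEFAULT_HYPERPARAMS)
    if hyperparams:
        unknown_keys = set(hyperparams) - set(DEFAULT_HYPERPARAMS)
        if unknown_keys:
            raise ValidationError(f"unknown hyperparameters: {sorted(unknown_keys)}")
        params.update(hyperparams)

    counts = np.asarray(sink.to_numpy() if isinstance(sink, pd.Series) else sink)
    tau = len(sources.asv_ids)
    if counts.shape != (tau,):
        raise ValidationError("sink length does not match the source ASV universe")
    total = int(counts.sum())
    if total == 0:
        raise ValidationError("sink is empty")

    if isinstance(rng, np.random.Generator):
        generator = rng
    else:
        generator = np.random.default_rng(0 if rng is None else rng)

    depth = int(params["rarefaction_depth"])
    if depth:
        if depth > total:
            raise ValidationError(
                f"rarefaction_depth {depth} exceeds sink total {total}"
            )
        counts = generator.multivariate_hypergeometric(counts.astype(np.int64), depth)

    names = sources.source_names
    alpha_known = float(params["alpha_known"])
    phi = np.empty((len(names), tau))
    for k, name in enumerate(names):
        m = np.asarray(sources.profiles[name], dtype=np.float64)
        phi[k] = (m + alpha_known) / (m.sum() + alpha_known * tau)

    taxa = np.repeat(np.arange(tau, dtype=np.int64), counts.astype(np.int64))
    kernel_seed = int(generator.integers(2**31 - int(params["n_restarts"])))
    env_sum, taxon_source, total_draws = _gibbs_kernel(
        taxa,
        phi,
        tau,
        float(params["alpha_unknown"]),
        float(params["beta"]),
        bool(sources.include_unknown),
        int(params["n_restarts"]),
        int(params["n_burnin"]),
        int(params["n_draws"]),
        int(params["draw_spacing"]),
        kernel_seed,
    )

    all_names = names + ([UNKNOWN] if sources.include_unknown else [])
    mixing = pd.Series(env_sum / total_draws, index=all_names, name=sink_id)
    mixing /= mixing.sum()  # guard against accumulated rounding

    nonzero = counts > 0
    frac = taxon_source[nonzero]
    denom = frac.sum(axis=1, keepdims=True)
    asv_fractions = pd.DataFrame(
        frac / denom,
        index=[a for a, nz in zip(sources.asv_ids, nonzero) if nz],
        columns=all_names,
    )
    return SourceAttribution(
        sink_id=sink_id,
        mixing=mixing,
        asv_fractions=asv_fractions,
        diagnostics={
            "n_restarts": int(params["n_restarts"]),
            "n_sweeps": int(params["n_burnin"])
            + int(params["n_draws"]) * int(params["draw_spacing"]),
            "rarefaction_depth": depth,
            "n_reads": int(counts.sum()),
            "n_draws_total": int(total_draws),
        },
    )


# ---------------------------------------------------------------------------
# Source construction and table correction
# ---------------------------------------------------------------------------

def contaminant_profile_source(
    table: AsvTable,
    reference: ExpectedReference,
    sample_ids: Sequence[str],
) -> np.ndarray:
    """Pooled contaminant profile: the listed (diluted) samples with every
    expected ASV zeroed out, summed into one count vector."""
    sub = table.subset_samples(list(sample_ids)).frame
    pooled = sub.sum(axis=1)
    pooled[pooled.index.isin(reference.id_set)] = 0
    return pooled.to_numpy()


def build_source_set(
    table: AsvTable,
    reference: ExpectedReference,
    control_sample_ids: Sequence[str],
    scenario: str,
    case: int,
    mock_sample_id: str | None = None,
    diluted_sample_ids: Sequence[str] | None = None,
) -> SourceSet:
    """Assemble source environments for a scenario/case combination.

    Scenario "defined_experimental_source": the experimental environment
    is known — a mock source built from the undiluted sample restricted
    to the expected ASVs, plus contaminant sources (case 1: pooled
    contaminant profile + negative control; case 2: negative control
    only).  Scenario "undefined_experimental_source": contaminant sources
    only, with the unknown source standing in for the (unmodeled)
    experimental environment.
    """
    if scenario not in ("defined_experimental_source", "undefined_experimental_source"):
        raise ValidationError(f"unknown scenario {scenario!r}")
    if case not in (1, 2):
        raise ValidationError(f"case must be 1 or 2, got {case}")
    if not control_sample_ids:
        raise ValidationError("at least one control sample id is required")
    frame = table.frame
    controls = frame[list(control_sample_ids)].sum(axis=1).to_numpy()
    sinks = [
        s for s in table.sample_ids if s not in set(control_sample_ids)
    ]
    if diluted_sample_ids is None:
        diluted_sample_ids = [s for s in sinks if s != (mock_sample_id or sinks[0])]
    profiles: dict[str, np.ndarray] = {}
    if scenario == "defined_experimental_source":
        mock_sample = mock_sample_id or sinks[0]
        mock_counts = frame[mock_sample].copy()
        mock_counts[~mock_counts.index.isin(reference.id_set)] = 0
        profiles["mock"] = mock_counts.to_numpy()
    if case == 1:
        profiles["contaminant"] = contaminant_profile_source(
            table, reference, diluted_sample_ids
        )
    profiles["negative_control"] = controls
    return SourceSet(
        asv_ids=tuple(table.asv_ids), profiles=profiles, include_unknown=True
    )


def sourcetracker_correct(
    table: AsvTable,
    attributions: Mapping[str, SourceAttribution],
    scenario: str,
    experimental_source_name: str | None = None,
    call_threshold: float = 0.5,
) -> "RemovalResult":
    """Turn per-sample attributions into a proportional removal result.

    Scenario "defined_experimental_source": the retained fraction of an
    ASV is its attributed fraction to ``experimental_source_name``.
    Scenario "undefined_experimental_source": the retained fraction is
    the fraction attributed to the unknown source (everything predicted
    to come from a contaminant source is removed).  Binary calls are
    derived by thresholding the retained fraction at ``call_threshold``
    (an ASV is removed iff its retained fraction is strictly below it).
    """
    from .removal_methods import RemovalResult

    if scenario == "defined_experimental_source":
        if not experimental_source_name:
            raise ValidationError(
                "scenario 'defined_experimental_source' requires "
                "experimental_source_name"
            )
        target = experimental_source_name
    elif scenario == "undefined_experimental_source":
        target = UNKNOWN
    else:
        raise ValidationError(f"unknown scenario {scenario!r}")

    sample_ids = list(attributions)
    retained = pd.DataFrame(
        1.0, index=table.asv_ids, columns=sample_ids
    )  # absent ASVs: no-op
    for s, attribution in attributions.items():
        if target not in attribution.mixing.index:
            raise ValidationError(
                f"source {target!r} not present in attribution for sample {s!r}"
            )
        retained.loc[attribution.asv_fractions.index, s] = attribution.asv_fractions[
            target
        ]
    kept = retained >= call_threshold
    return RemovalResult(
        method_name="sourcetracker",
        params={
            "scenario": scenario,
            "experimental_source_name": experimental_source_name,
            "call_threshold": call_threshold,
        },
        retained_fraction=retained,
        kept=kept,
    )
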