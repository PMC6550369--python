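"""Seeded mock-community dilution-series simulator with known ground truth.

The simulator emulates the structure of a low-biomass positive-control
experiment: a mock community of known bacteria (9 ASVs from 8 species,
one species split into two sequence variants) is serially diluted by a
fixed factor while a constant background of reagent-contaminant DNA is
introduced at every extraction/PCR step.  Deeper dilutions therefore
carry a larger *fraction* of contaminant reads even though the absolute
amount of contaminant template is constant.

Two-compartment template model
------------------------------
With mock template ``M0 * factor**(-d)`` at dilution round ``d`` and a
constant contaminant template ``C`` per reaction, the expected
contaminant read fraction is

    f_d = C / (C + M0 * factor**(-d))

which is 0 when C = 0, 1 when M0 = 0, and strictly increasing in d.
Reads for each dilution sample are drawn multinomially from the mixture
``(1 - f_d) * mock_profile + f_d * contaminant_profile``; each read is
then independently replaced with probability ``crosstalk_rate`` by a read
from a sample-private cross-talk pool (emulating barcode mis-assignment,
which produces low-count ASVs seen in a single sample).  The final
contaminant read count in a sample of depth N is therefore exactly
``Binomial(N, 1 - (1 - f_d) * (1 - crosstalk_rate))``.

The negative control draws reads from the contaminant profile restricted
to the subset of contaminants shared with the control, with a small
fraction ``negative_control_mock_leak`` of reads leaking in from a few
mock ASVs (cross-contamination / barcode cross talk into the blank).

DNA concentrations emulate a spectrophotometer reading proportional to
total template, with additive Gaussian noise and an instrument floor.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .community_data import (
    AsvTable,
    ExpectedReference,
    SampleMetadata,
    SampleType,
    ValidationError,
)


class ConfigError(ValueError):
    """Raised for invalid simulation configuration."""


#: Species of the default 8-member whole-cell mock community; the third
#: (Salmonella enterica) amplifies as two sequence variants.
DEFAULT_MOCK_SPECIES = (
    "Pseudomonas_aeruginosa",
    "Escherichia_coli",
    "Salmonella_enterica",
    "Lactobacillus_fermentum",
    "Enterococcus_faecalis",
    "Staphylococcus_aureus",
    "Listeria_monocytogenes",
    "Bacillus_subtilis",
)
SPLIT_SPECIES_INDEX = 2  # Salmonella: one species, two ASVs


def derive_seed(base_seed: int, *keys: object) -> int:
    """Derive a reproducible child seed (< 2**31) from a base seed and keys.

    Keyed by content (not call order) so adding a method or sample does
    not perturb the random stream of the others.
    """
    tag = zlib.crc32("/".join(str(k) for k in keys).encode())
    ss = np.random.SeedSequence([int(base_seed) & 0x7FFFFFFF, tag])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the dilution-series generator.

    Template amounts (``mock_template_d0``, ``contaminant_template``) are
    in arbitrary template units; only their ratio matters for read
    fractions, while ``concentration_gain`` converts template units to
    instrument concentration units (ng/µl).
    """

    n_mock_asvs: int = 9
    mock_profile_concentration: float = 100.0
    n_contaminant_asvs: int = 200
    contaminant_profile_shape: float = 0.25
    n_dilutions: int = 8
    dilution_factor: float = 3.0
    mock_template_d0: float = 400.0
    contaminant_template: float = 1.0
    reads_per_sample: tuple[int, ...] | int | None = None
    control_reads: int = 4000
    crosstalk_rate: float = 5e-4
    negative_control_mock_leak: float = 0.017
    n_control_mock_asvs: int = 3
    control_shared_fraction: float = 0.2
    concentration_gain: float = 0.05
    concentration_noise_sd: float = 0.02
    concentration_floor: float = 0.02
    split_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mock_asvs < 2:
            raise ConfigError("n_mock_asvs must be >= 2")
        if self.n_contaminant_asvs < 1:
            raise ConfigError("n_contaminant_asvs must be >= 1")
        if self.dilution_factor <= 1:
            raise ConfigError("dilution_factor must be > 1")
        if self.n_dilutions < 0:
            raise ConfigError("n_dilutions must be >= 0")
        if not (0 <= self.crosstalk_rate < 1):
            raise ConfigError("crosstalk_rate must be in [0, 1)")
        if not (0 <= self.negative_control_mock_leak < 1):
            raise ConfigError("negative_control_mock_leak must be in [0, 1)")
        if not (0 < self.control_shared_fraction <= 1):
            raise ConfigError("control_shared_fraction must be in (0, 1]")
        if self.mock_template_d0 < 0 or self.contaminant_template < 0:
            raise ConfigError("template amounts must be >= 0")
        if self.mock_profile_concentration <= 0:
            raise ConfigError("mock_profile_concentration must be > 0")
        if self.contaminant_profile_shape <= 0:
            raise ConfigError("contaminant_profile_shape must be > 0")
        if self.concentration_noise_sd < 0 or self.concentration_floor < 0:
            raise ConfigError("concentration noise/floor must be >= 0")
        if not (0 < self.split_fraction < 1):
            raise ConfigError("split_fraction must be in (0, 1)")
        if isinstance(self.reads_per_sample, int) and self.reads_per_sample <= 0:
            raise ConfigError("reads_per_sample must be > 0")
        if isinstance(self.reads_per_sample, tuple):
            if len(self.reads_per_sample) != self.n_dilutions + 1:
                raise ConfigError(
                    "reads_per_sample schedule must have n_dilutions + 1 entries"
                )
            if any(n <= 0 for n in self.reads_per_sample):
                raise ConfigError("reads_per_sample must be > 0")
        if self.control_reads <= 0:
            raise ConfigError("control_reads must be > 0")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def paper_scale(cls, seed: int = 0, **kwargs) -> "SimulationConfig":
        """Full-scale preset: 937-member contaminant pool, sequencing-run
        depths in the tens to hundreds of thousands of reads."""
        defaults = dict(
            n_contaminant_asvs=937,
            reads_per_sample=(
                251_419, 172_915, 250_861, 247_581, 216_341,
                136_081, 128_053, 41_071, 40_927,
            ),
            control_reads=60_000,
            seed=seed,
        )
        defaults.update(kwargs)
        return cls(**defaults)


@dataclass(frozen=True)
class GroundTruth:
    """Simulator-emitted truth: which ASVs are real, which contaminate, and
    the realized mock read fraction per sample."""

    expected_asv_ids: tuple[str, ...]
    contaminant_asv_ids: tuple[str, ...]
    origin: Mapping[str, str]  # contaminant id -> "reagent" | "crosstalk"
    shared_with_control: Mapping[str, bool]
    true_mock_fraction: Mapping[str, float]

    def __post_init__(self) -> None:
        expected = set(self.expected_asv_ids)
        contaminant = set(self.contaminant_asv_ids)
        if expected & contaminant:
            raise ValidationError(
                "expected and contaminant ASV sets must be disjoint"
            )

    def label_of(self, asv_id: str) -> str:
        return "mock" if asv_id in set(self.expected_asv_ids) else "contaminant"


@dataclass(frozen=True)
class SimulatedExperiment:
    table: AsvTable
    metadata: tuple[SampleMetadata, ...]
    truth: GroundTruth
    reference: ExpectedReference

    def __post_init__(self) -> None:
        meta_ids = {m.sample_id for m in self.metadata}
        missing = set(self.table.sample_ids) - meta_ids
        if missing:
            raise ValidationError(f"samples without metadata: {sorted(missing)}")
        if set(self.reference.expected_asv_ids) != set(self.truth.expected_asv_ids):
            raise ValidationError("reference must equal truth.expected_asv_ids")

    @property
    def dilution_sample_ids(self) -> list[str]:
        meta = {m.sample_id: m for m in self.metadata}
        return [s for s in self.table.sample_ids if not meta[s].is_control]

    @property
    def control_sample_ids(self) -> list[str]:
        meta = {m.sample_id: m for m in self.metadata}
        return [s for s in self.table.sample_ids if meta[s].is_control]


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

def mock_asv_ids(config: SimulationConfig) -> list[str]:
    """Identifiers of the expected mock ASVs, species-split included."""
    n = config.n_mock_asvs
    if n == len(DEFAULT_MOCK_SPECIES) + 1:
        ids: list[str] = []
        for i, sp in enumerate(DEFAULT_MOCK_SPECIES):
            if i == SPLIT_SPECIES_INDEX:
                ids.extend([f"mock_{sp}_v1", f"mock_{sp}_v2"])
            else:
                ids.append(f"mock_{sp}")
        return ids
    if n == 2:
        return ["mock_species_1", "mock_species_2"]
    ids = [f"mock_species_{i + 1}" for i in range(n - 1)]
    # one species slot split into two variants
    ids[-1:] = [f"mock_species_{n - 1}_v1", f"mock_species_{n - 1}_v2"]
    return ids


def make_mock_profile(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Relative-abundance profile of the mock ASVs.

    Near-even over species slots (Dirichlet with concentration
    ``mock_profile_concentration``; infinite concentration gives an
    exactly even profile), with one slot split unevenly into two sequence
    variants (``split_fraction`` : 1 - ``split_fraction``).
    """
    n = config.n_mock_asvs
    if n < 2:
        raise ConfigError("n_mock_asvs must be >= 2")
    n_slots = n if n == 2 else n - 1
    if np.isinf(config.mock_profile_concentration):
        slots = np.full(n_slots, 1.0 / n_slots)
    else:
        slots = rng.dirichlet(np.full(n_slots, config.mock_profile_concentration))
    if n == 2:
        return slots
    split_idx = SPLIT_SPECIES_INDEX if n == len(DEFAULT_MOCK_SPECIES) + 1 else n_slots - 1
    profile = np.empty(n)
    before = slots[:split_idx]
    after = slots[split_idx + 1:]
    split = slots[split_idx] * np.array([config.split_fraction, 1 - config.split_fraction])
    profile[:split_idx] = before
    profile[split_idx:split_idx + 2] = split
    profile[split_idx + 2:] = after
    return profile


def contaminant_asv_ids(config: SimulationConfig) -> list[str]:
    width = len(str(config.n_contaminant_asvs))
    return [f"contam_{i + 1:0{width}d}" for i in range(config.n_contaminant_asvs)]


def make_contaminant_profile(
    config: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Long-tailed relative-abundance profile of the reagent contaminants.

    Dirichlet with a small symmetric shape parameter: a few dominant taxa
    over a long tail, as reagent contamination presents in practice.
    Infinite shape gives a uniform profile.
    """
    k = config.n_contaminant_asvs
    if k == 1:
        return np.ones(1)
    if np.isinf(config.contaminant_profile_shape):
        return np.full(k, 1.0 / k)
    return rng.dirichlet(np.full(k, config.contaminant_profile_shape))


# ---------------------------------------------------------------------------
# Template model
# ---------------------------------------------------------------------------

def expected_contaminant_fraction(d: int, config: SimulationConfig) -> float:
    """Analytic contaminant template fraction f_d at dilution round d
    (before cross-talk): C / (C + M0 * factor**(-d))."""
    if d < 0:
        raise ValueError("dilution round must be >= 0")
    c = config.contaminant_template
    m = config.mock_template_d0 * config.dilution_factor ** (-d)
    if c == 0 and m == 0:
        raise ConfigError("contaminant fraction undefined when C = M0 = 0")
    return c / (c + m)


def expected_contaminant_read_fraction(d: int, config: SimulationConfig) -> float:
    """Analytic expected contaminant *read* fraction including cross-talk:
    1 - (1 - f_d) * (1 - crosstalk_rate)."""
    f = expected_contaminant_fraction(d, config)
    return 1.0 - (1.0 - f) * (1.0 - config.crosstalk_rate)


def read_depth_schedule(config: SimulationConfig) -> list[int]:
    """Reads per dilution sample D0..Dn.

    Default: geometrically decreasing from 12,000 to 2,000 with ±15%
    multiplicative jitter (echoing the non-monotone depths of real runs);
    reproducible from the config seed.
    """
    n = config.n_dilutions + 1
    if isinstance(config.reads_per_sample, tuple):
        return list(config.reads_per_sample)
    if isinstance(config.reads_per_sample, int):
        return [config.reads_per_sample] * n
    rng = np.random.default_rng(derive_seed(config.seed, "depth-schedule"))
    hi, lo = 12_000.0, 2_000.0
    depths = []
    for d in range(n):
        base = hi * (lo / hi) ** (d / max(config.n_dilutions, 1))
        depths.append(int(round(base * rng.uniform(0.85, 1.15))))
    return depths


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def _crosstalk_ids(sample_id: str, assignments: np.ndarray) -> list[str]:
    return [f"xt_{sample_id}_{k:03d}" for k in assignments]


def simulate_dilution_series(config: SimulationConfig) -> SimulatedExperiment:
    """Generate one seeded dilution-series experiment.

    Emits dilution samples D0..Dn plus one negative control "NC", with
    exact configured read depths, spectrophotometer-style concentrations,
    and a :class:`GroundTruth` recording every ASV's class and origin.
    Identical config (including seed) gives a bit-identical experiment.
    """
    mock_ids = mock_asv_ids(config)
    contam_ids = contaminant_asv_ids(config)

    profile_rng = np.random.default_rng(derive_seed(config.seed, "profiles"))
    mock_profile = make_mock_profile(config, profile_rng)
    contam_profile = make_contaminant_profile(config, profile_rng)

    # contaminants shared with the negative control
    n_shared = max(1, int(round(config.control_shared_fraction * len(contam_ids))))
    shared_idx = np.sort(
        profile_rng.choice(len(contam_ids), size=n_shared, replace=False)
    )
    shared = np.zeros(len(contam_ids), dtype=bool)
    shared[shared_idx] = True

    # mock ASVs that leak into the negative control
    n_leak = min(config.n_control_mock_asvs, len(mock_ids))
    leak_idx = np.sort(profile_rng.choice(len(mock_ids), size=n_leak, replace=False))

    depths = read_depth_schedule(config)
    n_mock, n_contam = len(mock_ids), len(contam_ids)

    columns: dict[str, np.ndarray] = {}
    crosstalk_counts: dict[str, dict[str, int]] = {}
    metadata: list[SampleMetadata] = []
    true_mock_fraction: dict[str, float] = {}

    for d in range(config.n_dilutions + 1):
        sample_id = f"D{d}"
        rng = np.random.default_rng(derive_seed(config.seed, "sample", sample_id))
        depth = depths[d]
        f_d = expected_contaminant_fraction(d, config)
        mixture = np.concatenate([(1 - f_d) * mock_profile, f_d * contam_profile])
        counts = rng.multinomial(depth, mixture / mixture.sum())
        # cross talk: each read independently replaced with prob epsilon
        n_xt = rng.binomial(depth, config.crosstalk_rate) if config.crosstalk_rate else 0
        if n_xt:
            removed = rng.multivariate_hypergeometric(counts, n_xt)
            counts = counts - removed
            # skewed assignment over a sample-private pool: few multi-read
            # ASVs, many singletons
            pool = rng.geometric(0.35, size=n_xt)
            xt: dict[str, int] = {}
            for asv in _crosstalk_ids(sample_id, pool):
                xt[asv] = xt.get(asv, 0) + 1
            crosstalk_counts[sample_id] = xt
        columns[sample_id] = counts
        mock_reads = int(counts[:n_mock].sum())
        true_mock_fraction[sample_id] = mock_reads / depth
        template = (
            config.mock_template_d0 * config.dilution_factor ** (-d)
            + config.contaminant_template
        )
        conc = config.concentration_gain * template + rng.normal(
            0.0, config.concentration_noise_sd
        )
        metadata.append(
            SampleMetadata(
                sample_id=sample_id,
                dilution_round=d,
                dna_concentration=max(config.concentration_floor, conc),
                sample_type=SampleType.DILUTION_SAMPLE,
            )
        )

    # negative control
    nc_id = "NC"
    rng = np.random.default_rng(derive_seed(config.seed, "sample", nc_id))
    nc_counts = np.zeros(n_mock + n_contam, dtype=np.int64)
    n_mock_reads = (
        rng.binomial(config.control_reads, config.negative_control_mock_leak)
        if config.negative_control_mock_leak
        else 0
    )
    if n_mock_reads:
        leak_profile = mock_profile[leak_idx]
        leak_counts = rng.multinomial(n_mock_reads, leak_profile / leak_profile.sum())
        nc_counts[leak_idx] += leak_counts
    restricted = contam_profile * shared
    nc_counts[n_mock:] = rng.multinomial(
        config.control_reads - n_mock_reads, restricted / restricted.sum()
    )
    columns[nc_id] = nc_counts
    true_mock_fraction[nc_id] = n_mock_reads / config.control_reads
    nc_conc = config.concentration_gain * config.contaminant_template + rng.normal(
        0.0, config.concentration_noise_sd
    )
    metadata.append(
        SampleMetadata(
            sample_id=nc_id,
            dilution_round=None,
            dna_concentration=max(config.concentration_floor, nc_conc),
            sample_type=SampleType.NEGATIVE_CONTROL,
        )
    )

    # assemble table: mock, reagent contaminants, then cross-talk ASVs
    xt_ids = sorted({asv for xt in crosstalk_counts.values() for asv in xt})
    asv_ids = mock_ids + contam_ids + xt_ids
    sample_ids = [m.sample_id for m in metadata]
    matrix = np.zeros((len(asv_ids), len(sample_ids)), dtype=np.int64)
    for j, s in enumerate(sample_ids):
        matrix[: n_mock + n_contam, j] = columns[s]
        for asv, c in crosstalk_counts.get(s, {}).items():
            matrix[asv_ids.index(asv), j] = c
    table = AsvTable.from_arrays(asv_ids, sample_ids, matrix).drop_empty_asvs()

    origin = {asv: "reagent" for asv in contam_ids}
    origin.update({asv: "crosstalk" for asv in xt_ids})
    shared_map = {asv: bool(shared[i]) for i, asv in enumerate(contam_ids)}
    shared_map.update({asv: False for asv in xt_ids})
    truth = GroundTruth(
        expected_asv_ids=tuple(mock_ids),
        contaminant_asv_ids=tuple(contam_ids + xt_ids),
        origin=origin,
        shared_with_control=shared_map,
        true_mock_fraction=true_mock_fraction,
    )
    taxon_labels = {
        asv: asv.removeprefix("mock_").rsplit("_v", 1)[0] for asv in mock_ids
    }
    reference = ExpectedReference(tuple(mock_ids), taxon_labels)
    return SimulatedExperiment(
        table=table, metadata=tuple(metadata), truth=truth, reference=reference
    )


def mock_profile_of(config: SimulationConfig) -> pd.Series:
    """The true mock relative-abundance profile as a Series keyed by ASV id
    (regenerated deterministically from the config)."""
    rng = np.random.default_rng(derive_seed(config.seed, "profiles"))
    return pd.Series(make_mock_profile(config, rng), index=mock_asv_ids(config))


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Write the ground-truth labels as TSV
    (asv_id, class, origin, shared_with_control)."""
    from pathlib import Path

    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("asv_id\tclass\torigin\tshared_with_control\n")
        for asv in truth.expected_asv_ids:
            fh.write(f"{asv}\tmock\texpected\tFalse\n")
        for asv in truth.contaminant_asv_ids:
            fh.write(
                f"{asv}\tcontaminant\t{truth.origin[asv]}\t"
                f"{truth.shared_with_control[asv]}\n"
            )
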