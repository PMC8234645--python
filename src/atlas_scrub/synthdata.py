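"""Synthetic expression atlases with planted defects and a truth manifest.

The generator emulates the data regime of a public Affymetrix expression
atlas: a wide probes x hybridizations matrix where samples carry one to three
replicate columns, healthy full-size columns (50,900 probes) sum to about
2.0e7, replicate pairs correlate almost perfectly, and a handful of columns
are defective in characteristic ways — corrupted replicates, whole studies
inserted on a log scale, column blocks pasted twice under different sample
names, repeated header names, and single-replicate samples.

Expression values follow a log-normal factor model: for probe g, sample s,
replicate t,

    log x_gst = mu_g + eta_gs + eps_gst

with a per-probe baseline ``mu_g`` (log-sd 0.6), a per-sample biological
effect ``eta_gs`` (log-sd 0.8, shared by the sample's replicates) and small
replicate noise ``eps`` (log-sd 0.05).  Sharing ``mu + eta`` makes healthy
replicate pairs correlate at ~0.995 on linear values, while redrawing ``eta``
for a corrupted replicate drops the pair correlation to ~0.25 — comfortably
either side of the 0.90 acceptance threshold.  (Keeping the log-scale spread
moderate matters: the sample Pearson correlation of very heavy-tailed
log-normals converges slowly, so wilder tails would make healthy pairs
fluctuate below their population correlation.)  Optional gene
modules replace the independent sample effect with a shared latent factor per
sample, giving within-module co-expression that survives rank and log
transforms.

Every planted defect is recorded in a :class:`TruthManifest`, so detector
precision/recall and the cleaning ledger can be checked exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .matrix_io import ExpressionMatrix

__all__ = [
    "FULL_PROBE_COUNT",
    "HEALTHY_FULL_SUM",
    "scaled_sum_threshold",
    "SampleSpec",
    "ModuleSpec",
    "SimConfig",
    "LowSumPlant",
    "BadReplicatePlant",
    "DuplicateDataPlant",
    "DefectSpec",
    "TruthManifest",
    "simulate_matrix",
    "mtgea_accounting_fixture",
]

#: Probe count of the full-size array the calibration targets.
FULL_PROBE_COUNT = 50_900
#: Column-sum a healthy full-size hybridization is calibrated to.
HEALTHY_FULL_SUM = 2.0e7


def scaled_sum_threshold(
    n_probes: int, full_threshold: float = 1e6
) -> float:
    """Low-sum threshold rescaled for a reduced probe count.

    The 1e6 cutoff is calibrated against full-size columns summing to ~2e7;
    when simulating fewer probes the per-probe level is unchanged, so sums and
    threshold both scale with ``n_probes / 50900``.
    """
    return full_threshold * n_probes / FULL_PROBE_COUNT


@dataclass
class SampleSpec:
    """One sample and its replicate count (1-3 in real atlases)."""

    name: str
    n_replicates: int = 3

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError(f"sample {self.name!r}: replicate count must be >= 1")


@dataclass
class ModuleSpec:
    """A co-expressed gene module driven by one latent factor per sample.

    ``loading`` and ``idio_sd`` split the sample-effect variance between the
    shared factor and probe-specific noise; within-module log-scale
    correlation is loading^2 / (loading^2 + idio_sd^2).
    """

    name: str
    n_probes: int
    loading: float = 0.9
    idio_sd: float = 0.3

    def __post_init__(self) -> None:
        if not 0 < self.loading:
            raise ValueError("module loading must be positive")
        target = self.loading**2 / (self.loading**2 + self.idio_sd**2)
        if not 0 < target < 1:
            raise ValueError("module correlation target must be in (0, 1)")


@dataclass
class SimConfig:
    """Shape and noise model of the simulated atlas."""

    samples: list[SampleSpec]
    n_probes: int = 5000
    probe_sd: float = 0.6
    sample_sd: float = 0.8
    noise_sd: float = 0.05
    modules: list[ModuleSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        names = [s.name for s in self.samples]
        if len(set(names)) != len(names):
            raise ValueError("sample names must be unique in the plan")
        if sum(m.n_probes for m in self.modules) > self.n_probes:
            raise ValueError("modules request more probes than available")

    @property
    def mean_per_probe(self) -> float:
        """Per-probe expected value; keeps healthy sums at ~2e7 full-scale."""
        return HEALTHY_FULL_SUM / FULL_PROBE_COUNT

    @property
    def log_mu(self) -> float:
        # E[exp(N(mu, s^2))] = exp(mu + s^2/2); solve for the target mean
        total_var = self.probe_sd**2 + self.sample_sd**2 + self.noise_sd**2
        return math.log(self.mean_per_probe) - total_var / 2.0


@dataclass
class LowSumPlant:
    """Collapse a sample's columns: scale them or insert them on a log scale."""

    sample: str
    factor: float | None = None
    log_base: float | None = None

    def __post_init__(self) -> None:
        if (self.factor is None) == (self.log_base is None):
            raise ValueError("specify exactly one of factor / log_base")
        if self.factor is not None and not 0 < self.factor < 1:
            raise ValueError("scale factor must be in (0, 1)")


@dataclass
class BadReplicatePlant:
    """Corrupt ``n_bad`` replicates of a sample by independent redraw.

    The redraw keeps the marginal distribution (hence the column sum) but
    destroys the shared sample effect, so the low-sum and low-correlation
    detectors stay orthogonal.
    """

    sample: str
    n_bad: int = 1


@dataclass
class DuplicateDataPlant:
    """Copy the columns of ``source_samples`` onto ``target_samples`` exactly.

    Samples are paired positionally and must have matching replicate counts;
    the targets end up value-identical to the sources under different names.
    """

    source_samples: list[str]
    target_samples: list[str]


@dataclass
class DefectSpec:
    """All planted defects; targets must exist in the sample plan and the
    defect sets must be pairwise disjoint for exact accounting."""

    low_sum: list[LowSumPlant] = field(default_factory=list)
    bad_replicates: list[BadReplicatePlant] = field(default_factory=list)
    duplicate_data: list[DuplicateDataPlant] = field(default_factory=list)
    duplicate_names: list[str] = field(default_factory=list)


@dataclass
class TruthManifest:
    """Ground truth for one simulated matrix.

    ``column_categories[i]`` is the planted defect of column ``i`` —
    ``healthy``, ``bad_replicate``, ``low_sum``, ``duplicate_data`` (both the
    copy and its source) or ``duplicate_name`` (the repeated occurrence) —
    and ``module_of_probe`` maps probe ids to module names for module members.
    ``means`` is the companion sample-level means matrix (means of the linear
    values, as deposited alongside real atlases even for log-inserted
    studies).
    """

    column_labels: list[str]
    column_samples: list[str]
    column_categories: list[str]
    module_of_probe: dict[str, str]
    seed: int
    config_echo: dict
    means: ExpressionMatrix | None = None

    def columns_with(self, category: str) -> list[int]:
        return [
            i for i, c in enumerate(self.column_categories) if c == category
        ]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "config": self.config_echo,
            "columns": [
                {"index": i, "label": lab, "sample": s, "category": c}
                for i, (lab, s, c) in enumerate(
                    zip(
                        self.column_labels,
                        self.column_samples,
                        self.column_categories,
                    )
                )
            ],
            "module_of_probe": dict(self.module_of_probe),
        }


def _probe_ids(n: int) -> list[str]:
    # synthetic Affymetrix-style probeset ids
    return [f"Msy.{i + 1:05d}.1.S1_at" for i in range(n)]


def simulate_matrix(
    config: SimConfig,
    defects: DefectSpec | None = None,
    seed: int = 0,
    with_means: bool = True,
) -> tuple[ExpressionMatrix, TruthManifest]:
    """Simulate an atlas under ``config`` with ``defects`` planted.

    Deterministic given ``seed``.  Healthy replicate pairs reach Pearson
    >= 0.97 by construction; corrupted replicates fall below 0.5; log-inserted
    columns store ``max(log_b(x), 0)`` (clipped so the matrix stays
    non-negative; at the calibrated expression level under 0.1% of probes sit
    below 1).  The companion means matrix always averages the *linear* values,
    which is what makes log insertion detectable by the antilog test.
    """
    defects = defects or DefectSpec()
    rng = np.random.default_rng(seed)
    sample_by_name = {s.name: s for s in config.samples}

    for plant in defects.low_sum:
        if plant.sample not in sample_by_name:
            raise ValueError(f"low-sum plant targets unknown sample {plant.sample!r}")
    for plant in defects.bad_replicates:
        spec = sample_by_name.get(plant.sample)
        if spec is None:
            raise ValueError(
                f"bad-replicate plant targets unknown sample {plant.sample!r}"
            )
        if plant.n_bad > spec.n_replicates:
            raise ValueError(
                f"sample {plant.sample!r}: cannot corrupt {plant.n_bad} of "
                f"{spec.n_replicates} replicates"
            )
    for plant in defects.duplicate_data:
        for name in (*plant.source_samples, *plant.target_samples):
            if name not in sample_by_name:
                raise ValueError(f"duplicate plant targets unknown sample {name!r}")
        if len(plant.source_samples) != len(plant.target_samples):
            raise ValueError("duplicate plant needs equal-length source/target lists")
        for s, t in zip(plant.source_samples, plant.target_samples):
            if sample_by_name[s].n_replicates != sample_by_name[t].n_replicates:
                raise ValueError(
                    f"duplicate plant {s!r} -> {t!r}: replicate counts differ"
                )
    for name in defects.duplicate_names:
        if name not in sample_by_name:
            raise ValueError(f"duplicate-name plant targets unknown sample {name!r}")

    n_probes = config.n_probes
    probe_ids = _probe_ids(n_probes)
    probe_base = config.log_mu + config.probe_sd * rng.standard_normal(n_probes)

    module_of_probe: dict[str, str] = {}
    module_slices: list[tuple[ModuleSpec, slice]] = []
    cursor = 0
    for mod in config.modules:
        sl = slice(cursor, cursor + mod.n_probes)
        module_slices.append((mod, sl))
        for i in range(sl.start, sl.stop):
            module_of_probe[probe_ids[i]] = mod.name
        cursor += mod.n_probes

    bad_by_sample = {p.sample: p.n_bad for p in defects.bad_replicates}
    low_by_sample = {p.sample: p for p in defects.low_sum}

    def draw_sample_effect() -> np.ndarray:
        """Per-probe sample effect: latent-factor for module probes,
        independent for the rest."""
        eta = config.sample_sd * rng.standard_normal(n_probes)
        for mod, sl in module_slices:
            z = rng.standard_normal()
            eta[sl] = mod.loading * z + mod.idio_sd * rng.standard_normal(
                sl.stop - sl.start
            )
        return eta

    columns: list[np.ndarray] = []
    linear_columns: list[np.ndarray] = []  # pre-log values, for the means
    labels: list[str] = []
    samples_of_col: list[str] = []
    categories: list[str] = []
    cols_of_sample: dict[str, list[int]] = {}

    for spec in config.samples:
        eta = draw_sample_effect()
        n_bad = bad_by_sample.get(spec.name, 0)
        cols_of_sample[spec.name] = []
        for t in range(spec.n_replicates):
            # corrupt the trailing n_bad replicates: independent redraw of the
            # sample effect, same marginal distribution
            corrupted = t >= spec.n_replicates - n_bad
            eff = draw_sample_effect() if corrupted else eta
            log_vals = (
                probe_base + eff + config.noise_sd * rng.standard_normal(n_probes)
            )
            vals = np.exp(log_vals)
            category = "bad_replicate" if corrupted else "healthy"
            plant = low_by_sample.get(spec.name)
            linear_vals = vals
            if plant is not None:
                category = "low_sum"
                if plant.factor is not None:
                    vals = vals * plant.factor
                    linear_vals = vals
                else:
                    # study uploaded on a log scale; the deposited means were
                    # computed from the original linear values
                    vals = np.maximum(
                        np.log(linear_vals) / math.log(plant.log_base), 0.0
                    )
            idx = len(columns)
            columns.append(vals)
            linear_columns.append(linear_vals)
            if spec.n_replicates == 1:
                label = spec.name
            else:
                label = f"{spec.name}_{t + 1}"
            labels.append(label)
            samples_of_col.append(spec.name)
            categories.append(category)
            cols_of_sample[spec.name].append(idx)

    # exact column copies under different sample names
    for plant in defects.duplicate_data:
        for src, dst in zip(plant.source_samples, plant.target_samples):
            for src_idx, dst_idx in zip(cols_of_sample[src], cols_of_sample[dst]):
                columns[dst_idx] = columns[src_idx].copy()
                linear_columns[dst_idx] = linear_columns[src_idx].copy()
                categories[dst_idx] = "duplicate_data"
                categories[src_idx] = "duplicate_data"

    # repeated header blocks (fresh draws; the defect is the name collision)
    for name in defects.duplicate_names:
        spec = sample_by_name[name]
        eta = draw_sample_effect()
        for t in range(spec.n_replicates):
            log_vals = (
                probe_base + eta + config.noise_sd * rng.standard_normal(n_probes)
            )
            vals = np.exp(log_vals)
            columns.append(vals)
            linear_columns.append(vals)
            labels.append(
                name if spec.n_replicates == 1 else f"{name}_{t + 1}"
            )
            samples_of_col.append(name)
            categories.append("duplicate_name")

    values = np.column_stack(columns)
    matrix = ExpressionMatrix(
        probe_ids=probe_ids, column_labels=labels, values=values
    )

    means_matrix: ExpressionMatrix | None = None
    if with_means:
        mean_cols = []
        mean_labels = []
        for spec in config.samples:
            idx = cols_of_sample[spec.name]
            mean_cols.append(
                np.column_stack([linear_columns[i] for i in idx]).mean(axis=1)
            )
            mean_labels.append(spec.name)
        means_matrix = ExpressionMatrix(
            probe_ids=probe_ids,
            column_labels=mean_labels,
            values=np.column_stack(mean_cols),
        )

    manifest = TruthManifest(
        column_labels=labels,
        column_samples=samples_of_col,
        column_categories=categories,
        module_of_probe=module_of_probe,
        seed=seed,
        config_echo={
            "n_probes": config.n_probes,
            "n_samples": len(config.samples),
            "probe_sd": config.probe_sd,
            "sample_sd": config.sample_sd,
            "noise_sd": config.noise_sd,
            "modules": [asdict(m) for m in config.modules],
            "defects": {
                "low_sum": [asdict(p) for p in defects.low_sum],
                "bad_replicates": [asdict(p) for p in defects.bad_replicates],
                "duplicate_data": [asdict(p) for p in defects.duplicate_data],
                "duplicate_names": list(defects.duplicate_names),
            },
        },
        means=means_matrix,
    )
    return matrix, manifest


# ---------------------------------------------------------------------------
# The accounting fixture: a 716-column atlas planting, category by category,
# the defect multiplicities of the reference cleaning exercise:
#   - 6 columns repeating the headers of two 3-replicate samples;
#   - ten samples with corrupted replicates removing 3/3/3/2/2/2/1/1/1/1
#     columns under the replicate rule (19 columns);
#   - two log-inserted studies of five 3-replicate samples each (30 columns);
#   - two 12-column study blocks duplicating each other pairwise (24 columns);
#   - thirty single-replicate samples (30 columns);
# for a total of 716 columns, 710 distinct headers, and 607 survivors.
# ---------------------------------------------------------------------------

#: (sample, replicate count, replicates corrupted). Samples losing all
#: replicates have every replicate redrawn (all pairs discordant); samples
#: losing one have a single corrupted replicate (two of three pairs fail, the
#: concordant pair is kept).
BAD_REPLICATE_PLAN: tuple[tuple[str, int, int], ...] = (
    ("RT_Myc_3wks_infection", 3, 3),
    ("GiantCell", 3, 3),
    ("GallTissue_GiantCell", 3, 3),
    ("RT_LCM_arbuscular", 2, 2),
    ("RT_LCM_cortical", 2, 2),
    ("RT_LCM_adjacent", 2, 2),
    ("Nod_Naut1_SalsC", 3, 1),
    ("RT_CRR_72hpi", 3, 1),
    ("RT_CRR_96hpi", 3, 1),
    ("Root_A17_control", 3, 1),
)

#: Two studies uploaded on a log2 scale, five 3-replicate samples each.
LOG_INSERTED_STUDIES: tuple[tuple[str, ...], ...] = (
    ("Myc_APP_P", "Myc_NAP_C", "Myc_ARB_A", "Myc_CMR_K", "Myc_EPI_E"),
    (
        "NodMeristem_ZoneI",
        "NodMeristem_ZoneII_prox",
        "NodMeristem_ZoneII_dist",
        "NodMeristem_Interzone",
        "NodMeristem_ZoneIII",
    ),
)

#: Two 12-column study blocks (four 3-replicate samples each); every column of
#: the second block is an exact copy of the corresponding first-block column.
DUPLICATE_BLOCK_SOURCES: tuple[str, ...] = (
    "Nod_PPT_0h",
    "Nod_PPT_3h",
    "Nod_PPT_12h",
    "Nod_PPT_48h",
)
DUPLICATE_BLOCK_TARGETS: tuple[str, ...] = (
    "HairyRoot_WT_Myc_CK",
    "HairyRoot_WT_Myc_T",
    "HairyRoot_RNAi_CK",
    "HairyRoot_RNAi_T",
)

#: Samples whose headers appear twice in the raw export (3 replicates each).
DUPLICATE_NAME_SAMPLES: tuple[str, ...] = ("Nod_10dpi", "Nod_14dpi")

N_SINGLETON_SAMPLES = 30


def mtgea_accounting_fixture(
    seed: int = 0,
    n_probes: int = 5000,
    with_means: bool = True,
) -> tuple[ExpressionMatrix, TruthManifest]:
    """The 716-column fixture mirroring the reference removal accounting.

    Healthy filler samples (three replicates each, plus one two-replicate
    sample to land exactly on 716 columns) pad the planted defects.  Running
    :func:`atlas_scrub.cleaner.clean` with ``r_min=0.90`` and
    ``sum_min=scaled_sum_threshold(n_probes)`` removes 103 columns —
    19 low-correlation, 30 low-sum, 24 duplicated-data, 30 singletons — after
    repairing the 6 duplicated headers, leaving 607.
    """
    samples: list[SampleSpec] = []
    defects = DefectSpec()

    for name, n_rep, n_bad in BAD_REPLICATE_PLAN:
        samples.append(SampleSpec(name, n_rep))
        defects.bad_replicates.append(BadReplicatePlant(name, n_bad))

    for study in LOG_INSERTED_STUDIES:
        for name in study:
            samples.append(SampleSpec(name, 3))
            defects.low_sum.append(LowSumPlant(name, log_base=2.0))

    for name in (*DUPLICATE_BLOCK_SOURCES, *DUPLICATE_BLOCK_TARGETS):
        samples.append(SampleSpec(name, 3))
    defects.duplicate_data.append(
        DuplicateDataPlant(
            list(DUPLICATE_BLOCK_SOURCES), list(DUPLICATE_BLOCK_TARGETS)
        )
    )

    # singleton names avoid a trailing _<digits> suffix so the default header
    # rule does not mistake them for replicates of one pseudo-sample
    for i in range(N_SINGLETON_SAMPLES):
        samples.append(SampleSpec(f"SingleShot{i + 1:02d}", 1))

    for name in DUPLICATE_NAME_SAMPLES:
        samples.append(SampleSpec(name, 3))
        defects.duplicate_names.append(name)

    # healthy filler to reach 716 columns: planted columns so far ...
    planted = (
        sum(n for _, n, _ in BAD_REPLICATE_PLAN)  # 27
        + 3 * sum(len(s) for s in LOG_INSERTED_STUDIES)  # 30
        + 3 * (len(DUPLICATE_BLOCK_SOURCES) + len(DUPLICATE_BLOCK_TARGETS))  # 24
        + N_SINGLETON_SAMPLES  # 30
        + 2 * 3 * len(DUPLICATE_NAME_SAMPLES)  # 12 (originals + repeats)
    )
    filler_cols = 716 - planted
    n_three_rep, remainder = divmod(filler_cols, 3)
    for i in range(n_three_rep):
        samples.append(SampleSpec(f"Healthy_{i + 1:03d}", 3))
    if remainder:
        # a two-replicate sample keeps the filler free of accidental singletons
        if remainder == 1:
            samples[-1] = SampleSpec(samples[-1].name, 2)
            samples.append(SampleSpec(f"Healthy_{n_three_rep + 1:03d}", 2))
        else:
            samples.append(SampleSpec(f"Healthy_{n_three_rep + 1:03d}", remainder))

    config = SimConfig(samples=samples, n_probes=n_probes)
    return simulate_matrix(config, defects, seed=seed, with_means=with_means)
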