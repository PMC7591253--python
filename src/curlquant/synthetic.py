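"""Synthetic data with planted ground truth for every pipeline stage.

Each generator emulates one experimental modality of a Reissner-fiber
body-axis study and returns the exact container its downstream quantifier
consumes, together with the planted truth, so parameter-recovery and
false-discovery properties can be asserted without any external data:

* RNA-seq counts — negative-binomial draws for 2 mutant alleles x
  2 phenotypes x 3 replicates with shared curled-down/up effects,
  allele-specific effects, family-level batch confounders and one optional
  low-reliability replicate;
* calcium traces — Poisson-timed transients (instantaneous rise,
  single-exponential decay) at 4 Hz for 4 min on a constant baseline, with
  genotype-dependent event rates;
* qPCR CTs — CT = intercept - log2(true abundance) + Gaussian noise per
  technical replicate;
* clutches — Mendelian genotype draws with a recessive curled phenotype
  and an optional treatment rescue probability;
* landmarks — three-point embryo outlines whose reflex ear-yolk-tail
  angle is an exact draw from a per-group Normal.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calcium import TraceSet
from .de import CountExperiment, ValidationError
from .morphometry import CROSSES, ClutchCounts, LandmarkSet
from .qpcr import CtTable

__all__ = [
    "CaSimConfig",
    "ClutchSimConfig",
    "CountSimConfig",
    "CtSimConfig",
    "LandmarkSimConfig",
    "simulate_calcium_traces",
    "simulate_clutch",
    "simulate_counts",
    "simulate_ct_values",
    "simulate_landmarks",
]

ALLELES = ("icm13", "icm15")


class ConfigError(ValidationError):
    """Raised for inconsistent simulator configuration."""


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------


@dataclass
class CountSimConfig:
    """Negative-binomial count simulator configuration.

    Counts follow NB(mean mu, variance mu + mu^2 * dispersion). Baseline
    per-gene abundances are uniform on ``baseline_log2_mean_range`` (log2
    CPM scale); curled samples of affected genes are shifted by the planted
    log2 fold change; every gene additionally receives a per-allele-family
    log-normal batch offset of sd ``allele_batch_sd`` (log2 scale), shared
    by all samples of that family — the confounder the consistency GLM must
    absorb. ``unreliable_replicate`` marks one sample whose per-gene means
    are scrambled by extra log-normal noise of log2-sd
    (noise_inflation - 1), emulating a replicate that fails quality
    control.
    """

    n_genes: int
    n_reps_per_cell: int = 3
    baseline_log2_mean_range: tuple[float, float] = (-2.0, 10.0)
    dispersion: float = 0.01
    n_shared_down: int = 0
    n_shared_up: int = 0
    shared_log2fc_down: float = -2.0
    shared_log2fc_up: float = 1.0
    n_allele_specific: int = 0
    allele_specific_log2fc: float = -2.0
    allele_batch_sd: float = 0.25
    unreliable_replicate: tuple[str, str, int] | None = None
    noise_inflation: float = 1.0
    library_size_range: tuple[int, int] = (20_000_000, 40_000_000)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.n_reps_per_cell < 1:
            raise ConfigError("n_genes and n_reps_per_cell must be positive")
        planted = self.n_shared_down + self.n_shared_up + self.n_allele_specific
        if min(self.n_shared_down, self.n_shared_up, self.n_allele_specific) < 0:
            raise ConfigError("gene-class counts must be nonnegative")
        if planted > self.n_genes:
            raise ConfigError(
                f"planted gene classes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if self.shared_log2fc_down >= 0:
            raise ConfigError("shared_log2fc_down must be negative")
        if self.shared_log2fc_up <= 0:
            raise ConfigError("shared_log2fc_up must be positive")
        if self.allele_batch_sd < 0:
            raise ConfigError("allele_batch_sd must be >= 0")
        if self.noise_inflation < 1:
            raise ConfigError("noise_inflation must be >= 1")
        lo, hi = self.library_size_range
        if lo < 1 or hi < lo:
            raise ConfigError("invalid library_size_range")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mu, dispersion) with variance mu + mu^2*dispersion; dispersion 0 is deterministic."""
    if dispersion == 0:
        return np.rint(mu).astype(np.int64)
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p).astype(np.int64)


def simulate_counts(config: CountSimConfig) -> tuple[CountExperiment, pd.DataFrame]:
    """Draw a 2-allele x 2-phenotype count experiment with planted effects.

    Returns the experiment and a truth table with one row per gene:
    ``gene_class`` in {shared_down, shared_up, allele_specific, null},
    the planted ``log2fc`` and, for allele-specific genes, the
    ``target_allele`` carrying the effect.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    width = len(str(n))
    genes = pd.Index([f"g{i + 1:0{width}d}" for i in range(n)], name="gene")

    base = rng.uniform(*config.baseline_log2_mean_range, size=n)
    klass = np.array(["null"] * n, dtype=object)
    log2fc = np.zeros(n)
    target = np.array([""] * n, dtype=object)
    i0 = 0
    klass[i0 : i0 + config.n_shared_down] = "shared_down"
    log2fc[i0 : i0 + config.n_shared_down] = config.shared_log2fc_down
    i0 += config.n_shared_down
    klass[i0 : i0 + config.n_shared_up] = "shared_up"
    log2fc[i0 : i0 + config.n_shared_up] = config.shared_log2fc_up
    i0 += config.n_shared_up
    for j in range(config.n_allele_specific):
        klass[i0 + j] = "allele_specific"
        log2fc[i0 + j] = config.allele_specific_log2fc
        target[i0 + j] = ALLELES[j % 2]

    batch = rng.normal(0.0, config.allele_batch_sd, size=(n, len(ALLELES)))

    columns: dict[str, np.ndarray] = {}
    sheet_rows = []
    for a_idx, allele in enumerate(ALLELES):
        for phen in ("straight", "curled"):
            for rep in range(1, config.n_reps_per_cell + 1):
                log2_rel = base + batch[:, a_idx]
                if phen == "curled":
                    affected = (klass == "shared_down") | (klass == "shared_up")
                    affected |= (klass == "allele_specific") & (target == allele)
                    log2_rel = log2_rel + np.where(affected, log2fc, 0.0)
                if config.unreliable_replicate == (allele, phen, rep):
                    extra_sd = config.noise_inflation - 1.0
                    log2_rel = log2_rel + rng.normal(0.0, extra_sd, size=n)
                rel = 2.0 ** log2_rel
                frac = rel / rel.sum()
                lib = rng.integers(*config.library_size_range, endpoint=True)
                mu = frac * lib
                columns[f"{allele}_{phen}_r{rep}"] = _nb_draw(rng, mu, config.dispersion)
                sheet_rows.append(
                    {
                        "sample": f"{allele}_{phen}_r{rep}",
                        "allele": allele,
                        "phenotype": phen,
                        "replicate": rep,
                    }
                )

    counts = pd.DataFrame(columns, index=genes)
    sheet = pd.DataFrame(sheet_rows).set_index("sample")
    truth = pd.DataFrame(
        {"gene_class": klass, "log2fc": log2fc, "target_allele": target}, index=genes
    )
    return CountExperiment(counts=counts, sheet=sheet), truth


# ---------------------------------------------------------------------------
# calcium traces
# ---------------------------------------------------------------------------


@dataclass
class CaSimConfig:
    """Event-driven fluorescence trace simulator.

    Transients are Poisson-timed instantaneous rises of ``amplitude_dff``
    decaying exponentially with ``decay_tau`` seconds, on a constant
    baseline; ``rate_scaling_by_group`` scales the event rate per group
    (e.g. ``{"mutant": 0.5}`` halves the mutant rate). ``noise_sd`` is in
    raw fluorescence units.
    """

    n_cells: int
    sampling_rate: float = 4.0
    duration: float = 240.0
    baseline_f: float = 100.0
    event_rate: float = 4.0  # events/min per cell
    amplitude_dff: float = 1.0
    decay_tau: float = 2.0
    noise_sd: float = 2.0
    rate_scaling_by_group: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ConfigError("n_cells must be positive")
        if self.baseline_f <= 0:
            raise ConfigError("baseline_f must be positive")
        n_samples = self.duration * self.sampling_rate
        if abs(n_samples - round(n_samples)) > 1e-9:
            raise ConfigError("duration x sampling_rate must be an integer sample count")
        if min(self.event_rate, self.amplitude_dff, self.noise_sd) < 0:
            raise ConfigError("rates, amplitudes and noise must be >= 0")
        if self.decay_tau <= 0:
            raise ConfigError("decay_tau must be positive")
        if any(m < 0 for m in self.rate_scaling_by_group.values()):
            raise ConfigError("rate multipliers must be >= 0")


def simulate_calcium_traces(config: CaSimConfig, group_assignment) -> TraceSet:
    """Simulate one ROI trace per cell; groups set the event-rate multiplier.

    ``group_assignment`` is a sequence of group labels, one per cell. The
    returned TraceSet stores the planted truth per ROI: event times, event
    count and the noise-free ∫ΔF/F min⁻¹ (the oracle for recovery tests).
    """
    config.validate()
    groups = list(group_assignment)
    if len(groups) != config.n_cells:
        raise ConfigError(
            f"group_assignment has {len(groups)} labels for {config.n_cells} cells"
        )
    rng = np.random.default_rng(config.seed)
    n_samples = int(round(config.duration * config.sampling_rate))
    time = np.arange(n_samples) / config.sampling_rate

    cols: dict[str, np.ndarray] = {}
    meta_rows = []
    truth_rows = []
    width = len(str(config.n_cells))
    for i, group in enumerate(groups):
        roi = f"roi{i + 1:0{width}d}"
        mult = config.rate_scaling_by_group.get(group, 1.0)
        lam = config.event_rate * mult * config.duration / 60.0
        n_events = rng.poisson(lam)
        event_times = np.sort(rng.uniform(0.0, config.duration, size=n_events))
        dff = np.zeros(n_samples)
        for t0 in event_times:
            after = time >= t0
            dff[after] += config.amplitude_dff * np.exp(-(time[after] - t0) / config.decay_tau)
        f = config.baseline_f * (1.0 + dff)
        if config.noise_sd > 0:
            f = f + rng.normal(0.0, config.noise_sd, size=n_samples)
            f = np.maximum(f, 1e-9)
        cols[roi] = f
        meta_rows.append({"roi": roi, "roi_class": "ventral", "group": group})
        t_min = time / 60.0
        true_integral = float(np.trapezoid(dff, t_min) / (t_min[-1] - t_min[0]))
        truth_rows.append(
            {
                "roi": roi,
                "group": group,
                "n_events": int(n_events),
                "event_times": event_times,
                "true_integral_per_min": true_integral,
            }
        )

    traces = pd.DataFrame(cols, index=pd.Index(time, name="time_s"))
    roi_meta = pd.DataFrame(meta_rows).set_index("roi")
    truth = pd.DataFrame(truth_rows).set_index("roi")
    return TraceSet(traces=traces, roi_meta=roi_meta, ground_truth=truth)


# ---------------------------------------------------------------------------
# qPCR CT values
# ---------------------------------------------------------------------------


@dataclass
class CtSimConfig:
    """CT simulator: CT = intercept - log2(abundance) + N(0, ct_noise_sd)."""

    genes: list[str]
    reference_gene: str
    true_rel_abundance: dict[tuple[str, str], float]  # (gene, condition) -> abundance
    ct_intercept: float = 22.0
    tech_reps: int = 3
    ct_noise_sd: float = 0.2
    n_bio_reps: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.reference_gene not in self.genes:
            raise ConfigError("reference gene must appear in the gene list")
        if not 2 <= self.tech_reps <= 3:
            raise ConfigError("tech_reps must be 2 or 3")
        if self.ct_noise_sd < 0 or self.n_bio_reps < 1:
            raise ConfigError("ct_noise_sd >= 0 and n_bio_reps >= 1 required")
        conditions = {c for (_, c) in self.true_rel_abundance}
        if not conditions:
            raise ConfigError("true_rel_abundance is empty")
        for cond in conditions:
            if (self.reference_gene, cond) not in self.true_rel_abundance:
                raise ConfigError(
                    f"reference gene abundance undefined for condition {cond!r}"
                )
        for key, v in self.true_rel_abundance.items():
            if v <= 0:
                raise ConfigError(f"nonpositive abundance for {key}")

    @property
    def conditions(self) -> list[str]:
        return sorted({c for (_, c) in self.true_rel_abundance})


def simulate_ct_values(config: CtSimConfig) -> CtTable:
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows = []
    for cond in config.conditions:
        for bio in range(1, config.n_bio_reps + 1):
            for gene in config.genes:
                if (gene, cond) not in config.true_rel_abundance:
                    continue
                true_ct = config.ct_intercept - math.log2(
                    config.true_rel_abundance[(gene, cond)]
                )
                for tech in range(1, config.tech_reps + 1):
                    rows.append(
                        {
                            "gene": gene,
                            "condition": cond,
                            "bio_rep": bio,
                            "tech_rep": tech,
                            "ct": true_ct + rng.normal(0.0, config.ct_noise_sd),
                        }
                    )
    return CtTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# clutches
# ---------------------------------------------------------------------------


@dataclass
class ClutchSimConfig:
    """Mendelian clutch simulator with a recessive curled phenotype.

    Genotypes follow the cross (heterozygote incross: 1/4 wt, 1/2 het,
    1/4 hom); an embryo is curled iff homozygous and not rescued, each
    homozygote escaping with probability ``rescue_prob`` under treatment.
    """

    cross: str = "het_x_het"
    n_embryos_per_clutch: int = 60
    n_clutches: int = 4
    rescue_prob: float = 0.0
    treatment: str = "control"
    seed: int = 0

    def validate(self) -> None:
        if self.cross not in CROSSES:
            raise ConfigError(f"unknown cross {self.cross!r}; expected one of {CROSSES}")
        if self.n_embryos_per_clutch < 1 or self.n_clutches < 1:
            raise ConfigError("clutch sizes must be positive")
        if not 0 <= self.rescue_prob <= 1:
            raise ConfigError("rescue_prob must be a probability")


GENOTYPE_PROBS = {
    "het_x_het": (0.25, 0.5, 0.25),
    "hom_x_hom": (0.0, 0.0, 1.0),
    "het_x_hom": (0.0, 0.5, 0.5),
}


def simulate_clutch(config: ClutchSimConfig) -> tuple[list[ClutchCounts], pd.DataFrame]:
    """Draw genotypes and curled phenotypes for each clutch.

    Returns per-clutch counts plus a per-embryo table (clutch, genotype,
    curled) for genotype-resolved checks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    probs = GENOTYPE_PROBS[config.cross]
    genotypes = np.array(["wt", "het", "hom"])
    counts: list[ClutchCounts] = []
    embryo_rows = []
    for c in range(1, config.n_clutches + 1):
        geno = genotypes[rng.choice(3, size=config.n_embryos_per_clutch, p=probs)]
        rescued = rng.uniform(size=config.n_embryos_per_clutch) < config.rescue_prob
        curled = (geno == "hom") & ~rescued
        counts.append(
            ClutchCounts(
                clutch=f"clutch{c}",
                treatment=config.treatment,
                n_curled=int(curled.sum()),
                n_total=config.n_embryos_per_clutch,
            )
        )
        for g, cu in zip(geno, curled):
            embryo_rows.append({"clutch": f"clutch{c}", "genotype": g, "curled": bool(cu)})
    return counts, pd.DataFrame(embryo_rows)


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSimConfig:
    """Three-point landmark simulator with per-group angle distributions.

    Each embryo's target reflex angle is drawn from the group's
    Normal(angle_mean_deg, angle_sd_deg), clipped to (0, 360). The vertex
    sits at the origin, the ear at distance L1 on the rostral (-x) side,
    and the tail at distance L2 in the direction realising the target
    angle under the reflex convention; any three-point configuration with
    that angle is equivalent for the quantifier.
    """

    groups: dict[str, tuple[float, float]]  # group -> (mean_deg, sd_deg)
    n_per_group: int = 20
    segment_lengths: tuple[float, float] = (1.0, 1.5)
    seed: int = 0

    def validate(self) -> None:
        if not self.groups:
            raise ConfigError("no landmark groups configured")
        for g, (mean, sd) in self.groups.items():
            if not 0 < mean < 360:
                raise ConfigError(f"group {g!r}: angle mean must be in (0, 360)")
            if sd < 0:
                raise ConfigError(f"group {g!r}: angle sd must be >= 0")
        if self.n_per_group < 1:
            raise ConfigError("n_per_group must be positive")
        if min(self.segment_lengths) <= 0:
            raise ConfigError("segment lengths must be positive")


def landmarks_for_angle(
    angle_deg: float,
    embryo: str = "e1",
    group: str = "g",
    segment_lengths: tuple[float, float] = (1.0, 1.5),
) -> LandmarkSet:
    """Construct a canonical three-point configuration with the given reflex angle."""
    l1, l2 = segment_lengths
    phi = math.radians(180.0 + angle_deg)
    return LandmarkSet(
        embryo=embryo,
        group=group,
        ear=(-l1, 0.0),
        yolk_vertex=(0.0, 0.0),
        tail_tip=(l2 * math.cos(phi), l2 * math.sin(phi)),
    )


def simulate_landmarks(config: LandmarkSimConfig) -> list[LandmarkSet]:
    config.validate()
    rng = np.random.default_rng(config.seed)
    eps = 1e-9
    out: list[LandmarkSet] = []
    for group in sorted(config.groups):
        mean, sd = config.groups[group]
        angles = np.clip(
            rng.normal(mean, sd, size=config.n_per_group), eps, 360.0 - eps
        )
        for i, angle in enumerate(angles):
            out.append(
                landmarks_for_angle(
                    float(angle),
                    embryo=f"{group}_{i + 1:03d}",
                    group=group,
                    segment_lengths=config.segment_lengths,
                )
            )
    return out
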