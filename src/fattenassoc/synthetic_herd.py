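"""Synthetic fattening cohorts with the statistical structure the analysis assumes.

The generator emulates a commercial Holstein-bull fattening herd: each
animal enters the unit at a known calendar date and age, is weighed on a
fixed cadence (monthly by default) and has its dry-matter intake recorded
daily, until the last target body weight (450 kg by default) is passed.

Growth is simulated on a daily latent-gain scale,

    gain(day) = baseline + genotype + season(date) + animal + residual,

where the genotype term is the classical single-locus decomposition
(-a / d / +a for the first homozygote, heterozygote and second homozygote,
summed over markers), the animal term is a per-animal normal deviate and
the residual is a normal deviate redrawn for every weigh-to-weigh interval.
Weights observed at weigh days equal the latent trajectory, so a planted
additive effect of ``a`` kg/day moves interval ADWG by exactly ``a`` in
expectation.  Daily intake follows metabolic body weight,

    DMI(day) = coeff * W(day)^0.75 + genotype_intake + noise.

Genotypes are drawn from allele frequency ``p`` with an inbreeding-like
departure coefficient ``f``: genotype probabilities p^2+fpq, 2pq(1-f),
q^2+fpq.  The packaged defaults are the 15-marker panel of a published
296-bull Holstein cohort, with ``f`` per marker solved from the published
genotype counts so simulated cohorts show the same Hardy-Weinberg
disequilibrium structure.

All randomness flows from one integer seed; each animal has its own
substream keyed by animal index, so a cohort is bit-reproducible and
unchanged for the shared animals when only ``n_animals`` changes.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .traits import DEFAULT_TARGETS, season_at

__all__ = [
    "MarkerSpec",
    "GainModelSpec",
    "IntakeModelSpec",
    "HerdConfig",
    "Herd",
    "ConfigurationError",
    "draw_genotypes",
    "simulate_animal",
    "generate_herd",
    "write_herd",
    "read_herd",
    "default_markers",
]


class ConfigurationError(ValueError):
    """A generator parameter combination is infeasible."""


@dataclass(frozen=True)
class MarkerSpec:
    """One biallelic marker: frequencies, HWE departure and planted effects.

    ``allele_freq`` is the frequency of the lexically first allele.
    ``hwe_departure_f`` is an inbreeding-like coefficient: genotype
    probabilities are (p^2+fpq, 2pq(1-f), q^2+fpq); f=0 gives
    Hardy-Weinberg proportions, f=1 no heterozygotes, negative f an excess
    of heterozygotes.  ``effect_a``/``effect_d`` are the additive effect and
    dominance deviation planted on daily gain (kg/day); the ``intake_*``
    pair acts on daily DMI (kg/day).
    """

    name: str
    alleles: tuple[str, str]
    allele_freq: float
    hwe_departure_f: float = 0.0
    effect_a: float = 0.0
    effect_d: float = 0.0
    intake_effect_a: float = 0.0
    intake_effect_d: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.alleles
        if not (a < b):
            object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))
        if not (0.0 < self.allele_freq < 1.0):
            raise ConfigurationError(f"marker {self.name}: allele_freq must be in (0,1)")
        if not (-1.0 <= self.hwe_departure_f <= 1.0):
            raise ConfigurationError(f"marker {self.name}: f must be in [-1,1]")
        if min(self.genotype_probs()) < -1e-12:
            raise ConfigurationError(
                f"marker {self.name}: f={self.hwe_departure_f} gives a negative "
                f"genotype probability at p={self.allele_freq}"
            )

    def genotype_probs(self) -> tuple[float, float, float]:
        p = self.allele_freq
        q = 1.0 - p
        f = self.hwe_departure_f
        probs = (p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q)
        return tuple(max(x, 0.0) if x > -1e-12 else x for x in probs)

    @property
    def genotype_labels(self) -> tuple[str, str, str]:
        a, b = self.alleles
        return (a + a, a + b, b + b)

    def gain_values(self) -> np.ndarray:
        """Genotype effects on daily gain: (-a, d, +a)."""
        return np.array([-self.effect_a, self.effect_d, self.effect_a])

    def intake_values(self) -> np.ndarray:
        return np.array([-self.intake_effect_a, self.intake_effect_d, self.intake_effect_a])


@dataclass(frozen=True)
class GainModelSpec:
    """Daily latent-gain model parameters (all kg or kg/day)."""

    baseline_adwg: float = 0.9
    season_effects: dict = field(
        default_factory=lambda: {
            "winter": -0.03,
            "spring": 0.02,
            "summer": -0.02,
            "autumn": 0.03,
        }
    )
    animal_sd: float = 0.08
    residual_sd: float = 0.10
    initial_weight_mean: float = 85.0
    initial_weight_sd: float = 8.0

    def __post_init__(self) -> None:
        if self.baseline_adwg <= 0:
            raise ConfigurationError("baseline_adwg must be positive")
        if min(self.animal_sd, self.residual_sd, self.initial_weight_sd) < 0:
            raise ConfigurationError("standard deviations must be nonnegative")


@dataclass(frozen=True)
class IntakeModelSpec:
    """Daily DMI = intake_coefficient * W^0.75 + effects + N(0, noise_sd)."""

    intake_coefficient: float = 0.10
    noise_sd: float = 0.30

    def __post_init__(self) -> None:
        if self.intake_coefficient <= 0:
            raise ConfigurationError("intake_coefficient must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")


def default_markers() -> tuple[MarkerSpec, ...]:
    """The packaged 15-marker Holstein panel.

    Allele frequencies are count-derived from the packaged reference
    genotype counts; the HWE-departure coefficient per marker is solved so
    the expected genotype proportions equal the observed ones
    (f = 1 - het_obs / 2pq).  Planted effects default to zero.
    """
    counts = load_reference_counts()
    specs = []
    for rec in counts.to_dict("records"):
        n11, n12, n22 = int(rec["n_hom_first"]), int(rec["n_het"]), int(rec["n_hom_second"])
        n = n11 + n12 + n22
        p = (2 * n11 + n12) / (2 * n)
        f = 1.0 - (n12 / n) / (2 * p * (1 - p))
        specs.append(
            MarkerSpec(
                name=str(rec["marker"]),
                alleles=(str(rec["allele_first"]), str(rec["allele_second"])),
                allele_freq=p,
                hwe_departure_f=f,
            )
        )
    return tuple(specs)


def load_reference_counts() -> pd.DataFrame:
    """Published genotype counts for the 15-marker, 296-bull reference cohort."""
    with importlib.resources.files("fattenassoc.data").joinpath(
        "holstein_genotype_counts.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def load_reference_lsm() -> pd.DataFrame:
    """Published genotype least-square means for the significant marker-trait pairs."""
    with importlib.resources.files("fattenassoc.data").joinpath(
        "holstein_genotype_lsm.csv"
    ).open() as fh:
        return pd.read_csv(fh)


@dataclass(frozen=True)
class HerdConfig:
    """Cohort-level generator configuration."""

    n_animals: int = 296
    markers: tuple[MarkerSpec, ...] = field(default_factory=default_markers)
    start_date_range: tuple[date, date] = (date(2016, 1, 1), date(2016, 12, 31))
    weigh_interval_days: int = 30
    target_weights: tuple[float, ...] = DEFAULT_TARGETS
    gain_model: GainModelSpec = field(default_factory=GainModelSpec)
    intake_model: IntakeModelSpec = field(default_factory=IntakeModelSpec)
    age_at_start_mean: float = 100.0
    age_at_start_sd: float = 10.0
    seed: int = 0
    max_days: int = 3000

    def __post_init__(self) -> None:
        if self.n_animals < 1:
            raise ConfigurationError("n_animals must be >= 1")
        if self.weigh_interval_days < 1:
            raise ConfigurationError("weigh_interval_days must be >= 1")
        t = tuple(float(x) for x in self.target_weights)
        object.__setattr__(self, "target_weights", t)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ConfigurationError("target weights must strictly increase")


@dataclass
class Herd:
    """Generated cohort as the four raw tables the pipeline consumes."""

    animals: pd.DataFrame  # animal_id, start_date, age_at_start_days
    genotypes: pd.DataFrame  # animal_id, marker, genotype
    weights: pd.DataFrame  # animal_id, day, weight_kg
    feed: pd.DataFrame  # animal_id, day, dmi_kg
    config: HerdConfig | None = None


def _animal_rng(seed: int, animal_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1, animal_index)))


def _cohort_rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(0,)))


def draw_genotypes(spec: MarkerSpec, n: int, rng: np.random.Generator) -> list[str]:
    """Draw n genotype calls from the marker's (possibly out-of-HWE) proportions."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    probs = np.asarray(spec.genotype_probs(), dtype=float)
    probs = probs / probs.sum()
    idx = rng.choice(3, size=n, p=probs)
    labels = spec.genotype_labels
    return [labels[i] for i in idx]


def simulate_animal(
    config: HerdConfig,
    genotypes: dict[str, str],
    rng: np.random.Generator,
    start_date: date,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one animal's trajectory.

    Returns (weigh_days, weigh_weights, daily_dmi); daily_dmi[t] is the
    intake on day t, for t = 0 .. last weigh day - 1.
    """
    gm, im = config.gain_model, config.intake_model
    marker_by_name = {m.name: m for m in config.markers}
    g_gain = 0.0
    g_intake = 0.0
    for name, call in genotypes.items():
        m = marker_by_name[name]
        labels = m.genotype_labels
        j = labels.index("".join(sorted(call)))
        g_gain += m.gain_values()[j]
        g_intake += m.intake_values()[j]

    w0 = gm.initial_weight_mean + gm.initial_weight_sd * rng.standard_normal()
    w0 = max(w0, 30.0)
    u = gm.animal_sd * rng.standard_normal()

    interval = config.weigh_interval_days
    last_target = config.target_weights[-1]
    max_days = config.max_days

    # season effect per day, built in chunks of one weigh interval
    weights = [w0]
    w = w0
    daily_dmi: list[float] = []
    day = 0
    while True:
        resid = gm.residual_sd * rng.standard_normal()
        days = np.arange(day, day + interval)
        seasons = [season_at(start_date, int(t)) for t in days]
        season_eff = np.array([gm.season_effects.get(s, 0.0) for s in seasons])
        rates = gm.baseline_adwg + g_gain + u + resid + season_eff
        w_path = w + np.concatenate([[0.0], np.cumsum(rates)])  # length interval+1
        dmi = (
            im.intake_coefficient * np.maximum(w_path[:-1], 0.0) ** 0.75
            + g_intake
            + im.noise_sd * rng.standard_normal(interval)
        )
        daily_dmi.extend(np.maximum(dmi, 0.0).tolist())
        w = float(w_path[-1])
        day += interval
        weights.append(w)
        if w >= last_target:
            break
        if day > max_days:
            raise ConfigurationError(
                f"animal did not reach {last_target} kg within {max_days} days; "
                "check gain-model parameters"
            )
    weigh_days = np.arange(0, day + 1, interval)
    return weigh_days, np.array(weights), np.array(daily_dmi)


def generate_herd(config: HerdConfig | None = None, seed: int | None = None) -> Herd:
    """Generate a full cohort under ``config`` (seed overrides config.seed)."""
    config = config or HerdConfig()
    if seed is not None:
        config = replace(config, seed=int(seed))
    crng = _cohort_rng(config.seed)

    n = config.n_animals
    ids = [f"A{i + 1:04d}" for i in range(n)]
    d0, d1 = config.start_date_range
    span = (d1 - d0).days
    offsets = crng.integers(0, span + 1, size=n) if span > 0 else np.zeros(n, dtype=int)
    start_dates = [d0 + timedelta(days=int(o)) for o in offsets]
    ages = np.maximum(
        np.round(config.age_at_start_mean + config.age_at_start_sd * crng.standard_normal(n)),
        30,
    ).astype(int)

    geno_rows = []
    calls_by_animal: list[dict[str, str]] = [dict() for _ in range(n)]
    for m in config.markers:
        calls = draw_genotypes(m, n, crng)
        for i, c in enumerate(calls):
            calls_by_animal[i][m.name] = c
            geno_rows.append({"animal_id": ids[i], "marker": m.name, "genotype": c})

    w_ids: list[str] = []
    w_days: list[np.ndarray] = []
    w_kg: list[np.ndarray] = []
    f_ids: list[str] = []
    f_days: list[np.ndarray] = []
    f_kg: list[np.ndarray] = []
    for i in range(n):
        rng = _animal_rng(config.seed, i)
        wd, ww, dmi = simulate_animal(config, calls_by_animal[i], rng, start_dates[i])
        w_ids.extend([ids[i]] * len(wd))
        w_days.append(wd)
        w_kg.append(ww)
        f_ids.extend([ids[i]] * len(dmi))
        f_days.append(np.arange(len(dmi)))
        f_kg.append(dmi)

    animals = pd.DataFrame(
        {
            "animal_id": ids,
            "start_date": [d.isoformat() for d in start_dates],
            "age_at_start_days": ages,
        }
    )
    weights = pd.DataFrame(
        {
            "animal_id": w_ids,
            "day": np.concatenate(w_days).astype(int),
            "weight_kg": np.concatenate(w_kg),
        }
    )
    feed = pd.DataFrame(
        {
            "animal_id": f_ids,
            "day": np.concatenate(f_days).astype(int),
            "dmi_kg": np.concatenate(f_kg),
        }
    )
    return Herd(
        animals=animals,
        genotypes=pd.DataFrame(geno_rows),
        weights=weights,
        feed=feed,
        config=config,
    )


def write_herd(herd: Herd, directory: str | Path) -> None:
    """Write animals/genotypes/weights/feed CSVs; round-trips via read_herd."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    herd.animals.to_csv(directory / "animals.csv", index=False)
    herd.genotypes.to_csv(directory / "genotypes.csv", index=False)
    herd.weights.to_csv(directory / "weights.csv", index=False)
    herd.feed.to_csv(directory / "feed.csv", index=False)


def read_herd(directory: str | Path) -> Herd:
    """Read a herd directory written by :func:`write_herd`."""
    directory = Path(directory)
    return Herd(
        animals=pd.read_csv(directory / "animals.csv"),
        genotypes=pd.read_csv(directory / "genotypes.csv"),
        weights=pd.read_csv(directory / "weights.csv"),
        feed=pd.read_csv(directory / "feed.csv"),
    )
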