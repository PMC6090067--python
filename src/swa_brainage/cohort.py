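"""Synthetic mouse cohorts with age- and exercise-structured slow-wave activity.

Six experimental groups are modelled: three ages (6, 18, 24 months) crossed
with two housing conditions (sedentary control vs. voluntary running-wheel
exercise, "RW").  Each mouse contributes one 12-dimensional profile of NREM
slow-wave activity (SWA, EEG power in the delta band, reported in
uV^2/0.5 Hz), one value per hour of the 12-h baseline light period.

Within a group, profiles are drawn from a multivariate normal distribution
-- the same distributional assumption the supervised template analysis makes
-- so every downstream stage can be tested on cohorts whose generative
parameters are known exactly.  The default group means encode the published
between-group structure: SWA rises with age, falls with exercise, and the
control-minus-RW offsets are 47, 24.8 and 60.44 uV^2/0.5 Hz at 6, 18 and 24
months.  Only between-group differences (not absolute levels) are
constrained by the source data, so the young-control anchor level is a free,
documented parameter.

The module can also emit epoch-level power spectra (4-s epochs, 0.5-25 Hz at
0.25 Hz resolution) with a bout-structured hypnogram and artifact flags, so
the spectral-reduction stage can be exercised end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterator, List, Mapping, Optional

import numpy as np

# --- fixed geometry of a recording -----------------------------------------

N_HOURS = 12
EPOCH_SECONDS = 4
EPOCHS_PER_HOUR = 3600 // EPOCH_SECONDS  # 900
N_EPOCHS = N_HOURS * EPOCHS_PER_HOUR  # 10800

FREQ_LOW = 0.5
FREQ_HIGH = 25.0
FREQ_STEP = 0.25
#: Spectral bin centres, 0.5 to 25 Hz in 0.25-Hz steps (99 bins).
FREQUENCY_GRID = np.round(
    np.arange(FREQ_LOW, FREQ_HIGH + FREQ_STEP / 2, FREQ_STEP), 6
)

AGES = (6, 18, 24)
STATES = ("WAKE", "NREM", "REM")


@dataclass(frozen=True, order=True)
class ClassLabel:
    """One of the six age/exercise groups.

    ``exercise`` is True for running-wheel (RW) mice, False for sedentary
    controls ("C").  String form is e.g. ``"6C"`` or ``"18RW"``; the mapping
    between strings and (age, exercise) pairs is bijective.
    """

    age_months: int
    exercise: bool

    def __post_init__(self) -> None:
        if self.age_months not in AGES:
            raise ValueError(f"age_months must be one of {AGES}, got {self.age_months}")
        if not isinstance(self.exercise, bool):
            raise ValueError("exercise must be a bool")

    @property
    def short(self) -> str:
        return f"{self.age_months}{'RW' if self.exercise else 'C'}"

    def __str__(self) -> str:
        return self.short

    @classmethod
    def parse(cls, text: "str | ClassLabel") -> "ClassLabel":
        if isinstance(text, ClassLabel):
            return text
        t = str(text).strip().upper()
        for lab in CANONICAL_LABELS:
            if t == lab.short:
                return lab
        raise ValueError(f"unrecognized class label {text!r}; expected one of "
                         f"{[l.short for l in CANONICAL_LABELS]}")


#: The six groups in canonical order: 6C, 6RW, 18C, 18RW, 24C, 24RW.
CANONICAL_LABELS = tuple(
    ClassLabel(a, e) for a in AGES for e in (False, True)
)

#: Published cohort sizes: controls n = 11, 8, 9 and RW n = 9, 9, 8
#: at 6, 18 and 24 months respectively.
DEFAULT_COUNTS: Dict[ClassLabel, int] = {
    ClassLabel(6, False): 11,
    ClassLabel(6, True): 9,
    ClassLabel(18, False): 8,
    ClassLabel(18, True): 9,
    ClassLabel(24, False): 9,
    ClassLabel(24, True): 8,
}

#: Light-period mean SWA of the control groups (uV^2/0.5 Hz).  Only the
#: ordering (increasing with age) is data-constrained; the absolute anchor
#: of 600 for young controls is a package default.
DEFAULT_CONTROL_MEANS = {6: 600.0, 18: 680.0, 24: 760.0}

#: Control-minus-RW offset of light-period mean SWA per age (uV^2/0.5 Hz).
RW_REDUCTION = {6: 47.0, 18: 24.8, 24: 60.44}

#: Covariance scale at which the smallest between-group mean distance
#: exceeds ten times the largest within-group standard deviation along any
#: direction -- the strongly separated regime used by the supervised and
#: clustering benchmarks.
SEPARATED_SCALE = 0.0015


def hourly_shape(amplitude: float = 0.15) -> np.ndarray:
    """Within-light-period SWA time course as a multiplicative shape.

    A linear decline from ``1 + amplitude`` (hour 1) to ``1 - amplitude``
    (hour 12), mean exactly 1, mimicking homeostatic dissipation of sleep
    pressure across the rest phase.  ``amplitude = 0`` gives a flat profile.
    """
    if not 0 <= amplitude < 1:
        raise ValueError("amplitude must be in [0, 1)")
    h = np.arange(N_HOURS, dtype=float)
    return 1.0 + amplitude * (1.0 - 2.0 * h / (N_HOURS - 1))


@dataclass
class SWAProfile:
    """One mouse's hourly NREM SWA over the 12-h baseline light period."""

    mouse_id: str
    label: ClassLabel
    values: np.ndarray  # 12 hourly values, uV^2/0.5 Hz

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (N_HOURS,):
            raise ValueError(f"profile must have exactly {N_HOURS} values, got {v.shape}")
        if not np.all(np.isfinite(v)) or np.any(v <= 0):
            raise ValueError("profile values must be finite and strictly positive")
        self.values = v


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic cohort.

    Per group: sample count, 12-dim hourly mean vector (uV^2/0.5 Hz) and a
    12x12 symmetric positive-semidefinite covariance.  Draws below ``floor``
    are clipped there, since SWA is a power and must stay positive.
    """

    counts: Dict[ClassLabel, int]
    means: Dict[ClassLabel, np.ndarray]
    covariances: Dict[ClassLabel, np.ndarray]
    seed: int = 0
    floor: float = 1.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        keys = set(self.counts)
        if keys != set(self.means) or keys != set(self.covariances):
            raise ValueError("counts, means and covariances must share the same classes")
        if self.floor <= 0:
            raise ValueError("floor must be positive")
        for lab in keys:
            n = self.counts[lab]
            if int(n) != n or n < 1:
                raise ValueError(f"count for class {lab} must be a positive integer")
            mu = np.asarray(self.means[lab], dtype=float)
            if mu.shape != (N_HOURS,) or not np.all(np.isfinite(mu)) or np.any(mu <= 0):
                raise ValueError(f"mean vector for class {lab} must be 12 finite positive values")
            self.means[lab] = mu
            cov = np.asarray(self.covariances[lab], dtype=float)
            if cov.shape != (N_HOURS, N_HOURS):
                raise ValueError(f"covariance for class {lab} must be 12x12")
            if not np.allclose(cov, cov.T, atol=1e-10):
                raise ValueError(f"covariance for class {lab} is not symmetric")
            w = np.linalg.eigvalsh(cov)
            tol = 1e-10 * max(1.0, float(np.trace(cov)) / N_HOURS)
            if w.min() < -tol:
                raise ValueError(
                    f"covariance for class {lab} is not positive semidefinite "
                    f"(minimum eigenvalue {w.min():.3g})"
                )
            self.covariances[lab] = cov

    @property
    def labels(self) -> List[ClassLabel]:
        return sorted(self.counts)


def default_cohort_spec(
    scale: float = 1.0,
    *,
    seed: int = 0,
    counts: Optional[Mapping[ClassLabel, int]] = None,
    control_means: Optional[Mapping[int, float]] = None,
    rw_reduction: Optional[Mapping[int, float]] = None,
    decline_amplitude: float = 0.15,
    rel_sd: float = 0.08,
    correlation: float = 0.3,
    floor: float = 1.0,
) -> CohortSpec:
    """Packaged default cohort parameters.

    Group means are ``level * hourly_shape(decline_amplitude)`` where the
    control levels rise with age and the RW levels sit below their
    age-matched controls by the published offsets (47, 24.8, 60.44
    uV^2/0.5 Hz at 6, 18, 24 months).  Within-group covariance is
    exchangeable-correlation (rho = ``correlation``) with per-hour SD equal
    to ``rel_sd`` times the hourly mean, multiplied by ``scale``; ``scale``
    therefore sets the separation regime without touching the means.
    """
    if not (np.isfinite(scale) and scale > 0):
        raise ValueError("scale must be a positive real")
    if not 0 <= correlation < 1:
        raise ValueError("correlation must be in [0, 1)")
    if rel_sd <= 0:
        raise ValueError("rel_sd must be positive")
    cm = dict(DEFAULT_CONTROL_MEANS if control_means is None else control_means)
    rw = dict(RW_REDUCTION if rw_reduction is None else rw_reduction)
    cts = dict(DEFAULT_COUNTS if counts is None else counts)
    shape = hourly_shape(decline_amplitude)

    means: Dict[ClassLabel, np.ndarray] = {}
    covs: Dict[ClassLabel, np.ndarray] = {}
    rho_matrix = (1 - correlation) * np.eye(N_HOURS) + correlation * np.ones((N_HOURS, N_HOURS))
    for lab in cts:
        level = cm[lab.age_months] - (rw[lab.age_months] if lab.exercise else 0.0)
        mu = level * shape
        sd = rel_sd * mu
        covs[lab] = scale * np.outer(sd, sd) * rho_matrix
        means[lab] = mu
    return CohortSpec(counts=cts, means=means, covariances=covs, seed=seed, floor=floor)


def well_separated_spec(seed: int = 0, **kwargs) -> CohortSpec:
    """Default cohort in the strongly separated regime.

    Covariance is shrunk (``scale = SEPARATED_SCALE``) so that every
    between-group mean distance exceeds ten times the largest within-group
    SD along any direction; see :func:`separation_ratio`.
    """
    return default_cohort_spec(SEPARATED_SCALE, seed=seed, **kwargs)


def separation_ratio(spec: CohortSpec) -> float:
    """Smallest between-class mean distance over largest within-class SD.

    The SD is taken along the worst direction (square root of the largest
    covariance eigenvalue over all classes).  A ratio >= 10 is the
    "separation greatly exceeds scatter" regime.
    """
    labels = spec.labels
    dmin = min(
        float(np.linalg.norm(spec.means[a] - spec.means[b]))
        for i, a in enumerate(labels)
        for b in labels[i + 1:]
    )
    smax = max(
        math.sqrt(max(np.linalg.eigvalsh(spec.covariances[lab]).max(), 0.0))
        for lab in labels
    )
    if smax == 0:
        return math.inf
    return dmin / smax


def _class_rng(spec_seed: int, lab: ClassLabel, *extra: int) -> np.random.Generator:
    # Per-class child streams: adding or resizing one class never perturbs
    # the draws of another.
    return np.random.default_rng([spec_seed, lab.age_months, int(lab.exercise), *extra])


def simulate_profiles(spec: CohortSpec) -> List[SWAProfile]:
    """Draw a cohort of hourly SWA profiles from the spec's per-class MVNs.

    Deterministic for a given spec (including its seed).  Draws are clipped
    at ``spec.floor``.  Returned in canonical class order, mice numbered
    within class.
    """
    spec.validate()
    out: List[SWAProfile] = []
    for lab in spec.labels:
        rng = _class_rng(spec.seed, lab)
        draws = rng.multivariate_normal(
            spec.means[lab], spec.covariances[lab], size=spec.counts[lab], method="svd"
        )
        draws = np.clip(draws, spec.floor, None)
        for i, row in enumerate(draws):
            out.append(SWAProfile(f"{lab.short}-{i + 1:02d}", lab, row))
    return out


# --- epoch-level simulation --------------------------------------------------


@dataclass(frozen=True)
class HypnogramParams:
    """Bout-structured hypnogram model for the light period.

    Sleep/wake alternates in bouts with geometrically distributed lengths
    (means in 4-s epochs).  After each NREM bout a REM bout follows with
    probability ``rem_prob``.  Defaults give roughly two-thirds NREM during
    the light period, the rest-phase norm for mice.
    """

    wake_mean_epochs: float = 30.0  # 2 min
    nrem_mean_epochs: float = 75.0  # 5 min
    rem_mean_epochs: float = 15.0   # 1 min
    rem_prob: float = 0.5

    def validate(self) -> None:
        if self.nrem_mean_epochs <= 0:
            raise ValueError(
                "NREM bout mean must be positive: with no NREM epochs the "
                "hourly SWA average is undefined"
            )
        if self.wake_mean_epochs < 0 or self.rem_mean_epochs < 0:
            raise ValueError("bout means must be nonnegative")
        if not 0 <= self.rem_prob <= 1:
            raise ValueError("rem_prob must be in [0, 1]")


@dataclass
class EpochSpectrumSeries:
    """Epoch-level EEG power spectra with hypnogram labels for one mouse.

    ``power`` is (10800, 99): per 4-s epoch, power per 0.25-Hz bin on the
    0.5-25 Hz grid.  ``offsets`` are seconds from lights-on, strictly
    increasing by 4.
    """

    mouse_id: str
    label: ClassLabel
    freqs: np.ndarray
    power: np.ndarray
    states: np.ndarray     # '<U4' array of WAKE/NREM/REM
    artifact: np.ndarray   # bool
    offsets: np.ndarray    # int seconds

    def __post_init__(self) -> None:
        if self.power.shape != (len(self.offsets), len(self.freqs)):
            raise ValueError("power must be (n_epochs, n_bins)")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")
        d = np.diff(self.offsets)
        if len(d) and not np.all(d == EPOCH_SECONDS):
            raise ValueError("epoch offsets must increase by exactly 4 s")


def _geometric_len(rng: np.random.Generator, mean: float) -> int:
    if mean <= 0:
        return 0
    return int(rng.geometric(min(1.0, 1.0 / mean)))


def _simulate_hypnogram(rng: np.random.Generator, params: HypnogramParams) -> np.ndarray:
    states = np.empty(N_EPOCHS, dtype="<U4")
    pos = 0
    while pos < N_EPOCHS:
        for state, mean in (("WAKE", params.wake_mean_epochs),
                            ("NREM", params.nrem_mean_epochs)):
            n = _geometric_len(rng, mean)
            states[pos:pos + n] = state
            pos += n
            if pos >= N_EPOCHS:
                return states
        if rng.random() < params.rem_prob:
            n = _geometric_len(rng, params.rem_mean_epochs)
            states[pos:pos + n] = "REM"
            pos += n
    return states


def simulate_epoch_series(
    spec: CohortSpec,
    hypnogram: Optional[HypnogramParams] = None,
    artifact_rate: float = 0.0,
    noise_sd: float = 0.0,
) -> List[EpochSpectrumSeries]:
    """Generate epoch-level spectra for every mouse in the cohort (eager).

    See :func:`iter_epoch_series`; this simply materializes the full list
    (memory ~8.5 MB per mouse).
    """
    return list(iter_epoch_series(spec, hypnogram, artifact_rate, noise_sd))


def iter_epoch_series(
    spec: CohortSpec,
    hypnogram: Optional[HypnogramParams] = None,
    artifact_rate: float = 0.0,
    noise_sd: float = 0.0,
) -> Iterator[EpochSpectrumSeries]:
    """Lazily generate per-mouse epoch spectra series.

    Each mouse gets 10800 4-s epochs spanning the 12-h light period with a
    bout-structured hypnogram.  For a NREM epoch in hour h the delta-band
    (0.75-4.0 Hz) bins are set so the band's integrated power equals the
    class's hourly mean SWA for hour h times a mean-one lognormal noise
    factor (exactly equal when ``noise_sd = 0``).  WAKE and REM epochs carry
    reduced delta power; all epochs sit on a 1/f background outside the
    delta band.  Artifact flags are i.i.d. Bernoulli(``artifact_rate``).
    """
    spec.validate()
    params = hypnogram if hypnogram is not None else HypnogramParams()
    params.validate()
    if not 0 <= artifact_rate < 1:
        raise ValueError("artifact_rate must be in [0, 1)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")

    freqs = FREQUENCY_GRID
    delta = (freqs >= 0.75) & (freqs <= 4.0)
    n_delta = int(delta.sum())  # 14 bins spanning 3.5 Hz
    band_width = FREQ_STEP * n_delta
    background = 20.0 / freqs  # small 1/f floor, uV^2 per bin
    offsets = np.arange(N_EPOCHS, dtype=int) * EPOCH_SECONDS
    hour_of_epoch = offsets // 3600
    state_delta_factor = {"WAKE": 0.30, "NREM": 1.0, "REM": 0.25}

    for lab in spec.labels:
        hourly_mean = spec.means[lab]
        for m in range(spec.counts[lab]):
            rng = _class_rng(spec.seed, lab, m, 7)
            states = _simulate_hypnogram(rng, params)
            artifact = rng.random(N_EPOCHS) < artifact_rate
            power = np.tile(background, (N_EPOCHS, 1))
            target = hourly_mean[hour_of_epoch].astype(float)
            for s, f in state_delta_factor.items():
                target[states == s] *= f
            if noise_sd > 0:
                factor = np.exp(rng.normal(0.0, noise_sd, N_EPOCHS) - noise_sd**2 / 2)
                target = target * factor
            # per-bin value such that band-integrated power (per 0.5 Hz
            # units) equals the target: mean bin * 0.5 / 0.25 = target
            power[:, delta] = (target * (band_width / n_delta) / 0.5)[:, None]
            yield EpochSpectrumSeries(
                mouse_id=f"{lab.short}-{m + 1:02d}",
                label=lab,
                freqs=freqs,
                power=power,
                states=states,
                artifact=artifact,
                offsets=offsets.copy(),
            )
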