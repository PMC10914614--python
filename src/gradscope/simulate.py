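"""Truth-labelled synthetic gradients and infection time courses.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage has a no-download test surface with known ground
truth:

* **Gradient**: each complex class sediments as a Gaussian bump on the
  fraction index (discretized at j = 1..20 and renormalized so the bump
  carries the protein's gradient mass), plus a separate pellet
  compartment. A protein's clean row is its abundance times a mixture of
  a free-protein bump and its class bump. Measurement adds per-fraction
  technical scale factors (corrected later by the constant spike-in row),
  multiplicative lognormal noise with a fixed coefficient of variation,
  and hard dropout below a detection threshold.
* **Time course**: phage transcript classes switch on logistically with
  class-specific onset times (early < mid < late); host transcripts are
  constant, then mildly decaying. The global phage amplitude is calibrated
  so the expected phage share of coding reads at the final time point hits
  a configured target (default 40%). Realized counts are Poisson.

Randomness is drawn from per-row substreams of one global seed, so output
is reproducible independent of row order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .io import (
    N_FRACTIONS,
    AnnotationTable,
    CountsTimecourse,
    IntensityMatrix,
    REFERENCE_COMPLEXES,
)

SPIKE_IN_ID = "P02768"  # human serum albumin, the per-fraction standard

# substream name-spacing under the global seed
_PROTEIN_STREAM = 1
_SCALE_STREAM = 2
_TRANSCRIPT_STREAM = 3


# ---------------------------------------------------------------------------
# configuration


@dataclass
class GradientClass:
    """One protein class: a sedimentation bump and its bookkeeping.

    ``center=None`` marks a purely free class (no complexed pool).
    ``reference`` is the true machinery label used for recovery scoring;
    ``annotated`` says whether that label is exposed in the annotation
    table (host machinery is; planted phage binders are not — they are
    what the pipeline must discover).
    """

    label: str
    organism: str
    n: int
    center: float | None = None
    width: float = 1.0
    pellet_mass: float = 0.0
    reference: str = "none"
    annotated: bool = False

    def validate(self) -> None:
        if self.n < 1:
            raise ParameterError(f"class {self.label!r}: n must be >= 1")
        if self.organism not in ("host", "phage"):
            raise ParameterError(
                f"class {self.label!r}: organism must be host or phage"
            )
        if self.center is not None and not 1.0 <= self.center <= 20.0:
            raise ParameterError(
                f"class {self.label!r}: center must lie in [1, 20]"
            )
        if self.width <= 0.3:
            raise ParameterError(
                f"class {self.label!r}: width must be > 0.3 "
                "(sub-fraction widths are unidentifiable)"
            )
        if not 0.0 <= self.pellet_mass <= 1.0:
            raise ParameterError(
                f"class {self.label!r}: pellet_mass must be in [0, 1]"
            )
        if self.reference not in REFERENCE_COMPLEXES:
            raise ParameterError(
                f"class {self.label!r}: reference must be one of "
                f"{list(REFERENCE_COMPLEXES)}"
            )


@dataclass
class SimConfig:
    """Gradient-generator parameters. Defaults are the study conditions."""

    classes: list[GradientClass]
    free_center: float = 2.0
    free_width: float = 1.0
    free_fraction_per_protein: float = 0.1
    abundance_log10_range: tuple[float, float] = (8.3, 10.5)
    noise_cv: float = 0.2
    dropout_threshold: float = 1e-3  # relative to median positive signal
    fraction_scale_factor_sd: float = 0.3
    spike_in_level: float = 1e9
    seed: int = 42
    n_fractions: int = N_FRACTIONS  # fixed by the gradient geometry

    def validate(self) -> None:
        if self.n_fractions != N_FRACTIONS:
            raise ParameterError("n_fractions is fixed at 20")
        if not self.classes:
            raise ParameterError("classes must be non-empty")
        for c in self.classes:
            c.validate()
        if self.free_width <= 0.3:
            raise ParameterError("free_width must be > 0.3")
        if not 0.0 <= self.free_fraction_per_protein <= 1.0:
            raise ParameterError(
                "free_fraction_per_protein must be in [0, 1]"
            )
        lo, hi = self.abundance_log10_range
        if hi < lo:
            raise ParameterError("abundance_log10_range must be (lo, hi)")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if self.dropout_threshold < 0:
            raise ParameterError("dropout_threshold must be >= 0")
        if self.fraction_scale_factor_sd < 0:
            raise ParameterError("fraction_scale_factor_sd must be >= 0")
        if self.spike_in_level <= 0:
            raise ParameterError("spike_in_level must be > 0")


@dataclass
class TimecourseClass:
    """One transcript class: logistic onset (phage) or host baseline."""

    label: str
    genome: str
    n: int
    tau: float | None = None  # onset midpoint, minutes; None for host
    slope: float = 1.5  # logistic time scale, minutes
    amplitude: float = 1.0  # class-level rate multiplier
    transcript_ids: list[str] | None = None

    def validate(self) -> None:
        if self.n < 1:
            raise ParameterError(f"class {self.label!r}: n must be >= 1")
        if self.genome not in ("host", "phage"):
            raise ParameterError(
                f"class {self.label!r}: genome must be host or phage"
            )
        if self.genome == "phage" and self.tau is None:
            raise ParameterError(
                f"phage class {self.label!r} needs an onset time tau"
            )
        if self.tau is not None and self.slope <= 0:
            raise ParameterError(f"class {self.label!r}: slope must be > 0")
        if self.amplitude < 0:
            raise ParameterError(
                f"class {self.label!r}: amplitude must be >= 0"
            )
        if self.transcript_ids is not None and len(self.transcript_ids) != self.n:
            raise ParameterError(
                f"class {self.label!r}: transcript_ids length != n"
            )


@dataclass
class TimecourseConfig:
    """Time-course generator parameters. Defaults are the study conditions."""

    classes: list[TimecourseClass]
    timepoints: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0)
    abundance_sigma: float = 0.6  # lognormal spread of per-transcript rates
    reads_per_timepoint: float = 2e5
    target_phage_share_end: float = 0.40
    host_decay_rate: float = 0.05  # per minute, after onset
    host_decay_onset: float = 4.0  # minutes
    seed: int = 42

    def validate(self) -> None:
        if not self.classes:
            raise ParameterError("classes must be non-empty")
        for c in self.classes:
            c.validate()
        taus = [c.tau for c in self.classes if c.genome == "phage"]
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ParameterError(
                "phage class onset times must be strictly increasing "
                f"in class order; got {taus}"
            )
        if len(self.timepoints) < 2 or any(
            b <= a for a, b in zip(self.timepoints, self.timepoints[1:])
        ):
            raise ParameterError("timepoints must be strictly increasing")
        if not 0.0 < self.target_phage_share_end < 1.0:
            raise ParameterError("target_phage_share_end must be in (0, 1)")
        if self.abundance_sigma < 0 or self.reads_per_timepoint <= 0:
            raise ParameterError("bad abundance_sigma/reads_per_timepoint")
        if self.host_decay_rate < 0:
            raise ParameterError("host_decay_rate must be >= 0")


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class ProteinTruth:
    class_label: str
    organism: str
    reference: str  # true machinery label; "none" if not machinery
    annotated: bool
    w_free: float
    abundance: float
    center: float | None
    width: float
    pellet_mass: float


@dataclass
class TranscriptTruth:
    class_label: str
    genome: str
    tau: float | None
    rate: float  # per-transcript relative abundance a_i (before scaling)


@dataclass
class SimTruth:
    """Ground-truth records for every emitted row."""

    proteins: dict[str, ProteinTruth] = field(default_factory=dict)
    transcripts: dict[str, TranscriptTruth] = field(default_factory=dict)

    def annotation_table(self) -> AnnotationTable:
        """Annotations as a scientist would have them *before* the study:
        host machinery labelled, everything else 'none'."""
        ids, orgs, refs = [], [], []
        for pid, t in self.proteins.items():
            ids.append(pid)
            orgs.append(t.organism)
            refs.append(t.reference if t.annotated else "none")
        return AnnotationTable(
            protein_ids=ids, organism=orgs, reference_complex=refs
        )

    def machinery_proteins(self) -> dict[str, str]:
        """protein id -> true machinery label, for all complexed machinery
        members (the scoring set for assignment accuracy)."""
        return {
            pid: t.reference
            for pid, t in self.proteins.items()
            if t.reference != "none"
        }

    def planted_binders(self) -> list[str]:
        """Phage proteins planted as ribosome binders (truth 30S/50S)."""
        return [
            pid
            for pid, t in self.proteins.items()
            if t.organism == "phage" and t.reference in ("30S", "50S")
        ]

    def virion_like(self) -> list[str]:
        """Phage proteins planted as pellet-heavy virion-like."""
        return [
            pid
            for pid, t in self.proteins.items()
            if t.organism == "phage" and t.pellet_mass > 0.5
        ]


# ---------------------------------------------------------------------------
# gradient simulation


def _gaussian_bump(center: float, width: float) -> np.ndarray:
    """Gaussian density on fraction indices 1..20, renormalized to sum 1."""
    j = np.arange(1, N_FRACTIONS + 1, dtype=float)
    g = np.exp(-0.5 * ((j - center) / width) ** 2)
    return g / g.sum()


def _lognormal_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _protein_roster(cfg: SimConfig) -> list[tuple[str, GradientClass]]:
    roster = []
    for c in cfg.classes:
        for i in range(1, c.n + 1):
            roster.append((f"{c.organism}_{c.label}_{i:03d}", c))
    return roster


def simulate_gradient(cfg: SimConfig) -> tuple[IntensityMatrix, SimTruth]:
    """Generate a raw intensity matrix plus ground truth.

    Row i of the clean matrix is
    ``A_p * [w_free*g(j; mu_free, s_free) + w_c*g(j; mu_c, s_c)]`` over the
    20 fractions and ``A_p * w_c * pellet_mass_c`` in the pellet. The
    emitted matrix multiplies in lognormal measurement noise (CV =
    ``noise_cv``), zeroes values below the detection threshold (a fraction
    of the median positive signal, applied on the undistorted scale so
    detection does not depend on per-fraction technical factors), and
    finally applies per-fraction scale factors ``d_j`` shared with the
    constant spike-in row — exactly the distortion the spike-in correction
    removes.
    """
    cfg.validate()
    roster = _protein_roster(cfg)
    g_free = _gaussian_bump(cfg.free_center, cfg.free_width)

    n = len(roster)
    noisy = np.empty((n, N_FRACTIONS + 1), dtype=float)
    truth = SimTruth()
    for i, (pid, cls) in enumerate(roster):
        rng = np.random.default_rng([cfg.seed, _PROTEIN_STREAM, i])
        lo, hi = cfg.abundance_log10_range
        abundance = 10.0 ** rng.uniform(lo, hi)
        if cls.center is None:
            w_free, bump, pellet_mass = 1.0, np.zeros(N_FRACTIONS), 0.0
        else:
            w_free = cfg.free_fraction_per_protein
            bump = _gaussian_bump(cls.center, cls.width)
            pellet_mass = cls.pellet_mass
        w_c = 1.0 - w_free
        clean = np.empty(N_FRACTIONS + 1)
        clean[:N_FRACTIONS] = abundance * (w_free * g_free + w_c * bump)
        clean[N_FRACTIONS] = abundance * w_c * pellet_mass
        eps = _lognormal_noise(rng, cfg.noise_cv, N_FRACTIONS + 1)
        noisy[i] = clean * eps
        truth.proteins[pid] = ProteinTruth(
            class_label=cls.label,
            organism=cls.organism,
            reference=cls.reference,
            annotated=cls.annotated,
            w_free=w_free,
            abundance=abundance,
            center=cls.center,
            width=cls.width,
            pellet_mass=pellet_mass,
        )

    # detection limit on the undistorted scale
    if cfg.dropout_threshold > 0:
        positive = noisy[noisy > 0]
        if positive.size:
            thr = cfg.dropout_threshold * float(np.median(positive))
            noisy[noisy < thr] = 0.0

    # per-fraction technical scale factors, shared with the spike-in row
    scale_rng = np.random.default_rng([cfg.seed, _SCALE_STREAM])
    if cfg.fraction_scale_factor_sd > 0:
        d = scale_rng.lognormal(
            mean=0.0, sigma=cfg.fraction_scale_factor_sd, size=N_FRACTIONS + 1
        )
    else:
        d = np.ones(N_FRACTIONS + 1)

    values = np.vstack([noisy * d[np.newaxis, :], cfg.spike_in_level * d])
    matrix = IntensityMatrix(
        protein_ids=[pid for pid, _ in roster] + [SPIKE_IN_ID],
        values=values,
        organism=[cls.organism for _, cls in roster] + ["spike_in"],
        spike_in_id=SPIKE_IN_ID,
    )
    return matrix, truth


def default_gradient_config(seed: int = 42, **overrides) -> SimConfig:
    """The default simulated gradient: ~440 proteins, five host classes
    (free, RNAP, 30S, 50S, 70S/polysome), 8 planted phage ribosome
    binders, 6 pellet-heavy virion-like and 5 phage-polymerase-like
    proteins. Class centers follow the observed gradient geometry: free
    proteins in the first fractions, polymerase at fraction 5, ribosomal
    subunits and polysomes deeper."""
    classes = [
        GradientClass("free", "host", 310),
        GradientClass(
            "RNAP", "host", 8, center=5.0, width=1.0, pellet_mass=0.02,
            reference="RNAP", annotated=True,
        ),
        GradientClass(
            "30S", "host", 21, center=11.0, width=1.2, pellet_mass=0.02,
            reference="30S", annotated=True,
        ),
        GradientClass(
            "50S", "host", 33, center=14.0, width=1.2, pellet_mass=0.03,
            reference="50S", annotated=True,
        ),
        GradientClass(
            "70S_polysome", "host", 30, center=17.0, width=1.5,
            pellet_mass=0.05, reference="other", annotated=True,
        ),
        GradientClass("free", "phage", 21),
        GradientClass(
            "nvRNAP", "phage", 5, center=5.0, width=1.0, pellet_mass=0.02,
            reference="RNAP",
        ),
        GradientClass(
            "rib30", "phage", 3, center=11.0, width=1.2, pellet_mass=0.0,
            reference="30S",
        ),
        GradientClass(
            "rib50", "phage", 5, center=14.0, width=1.2, pellet_mass=0.0,
            reference="50S",
        ),
        GradientClass(
            "virion", "phage", 6, center=18.0, width=1.5, pellet_mass=0.8,
        ),
    ]
    return SimConfig(classes=classes, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# time-course simulation


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _phage_shape(t: np.ndarray, tau: float, slope: float) -> np.ndarray:
    """Logistic accumulation, anchored to zero at t=0 (pre-infection)."""
    return np.maximum(
        0.0, _logistic((t - tau) / slope) - _logistic(-tau / slope)
    )


def _host_shape(t: np.ndarray, rate: float, onset: float) -> np.ndarray:
    return np.where(t <= onset, 1.0, np.exp(-rate * (t - onset)))


def simulate_timecourse(
    cfg: TimecourseConfig,
) -> tuple[CountsTimecourse, SimTruth]:
    """Generate a transcript × time-point count table plus ground truth.

    Expected counts: host transcripts follow a constant-then-decaying
    baseline; phage transcripts follow class-wise logistic accumulation.
    The global phage amplitude is solved so that the *expected* phage
    share of reads at the last time point equals
    ``target_phage_share_end`` given the drawn per-transcript rates.
    Realized counts are Poisson.
    """
    cfg.validate()
    t = np.asarray(cfg.timepoints, dtype=float)
    roster: list[tuple[str, TimecourseClass]] = []
    for c in cfg.classes:
        if c.transcript_ids is not None:
            ids = list(c.transcript_ids)
        else:
            ids = [f"{c.genome}_{c.label}_{i:03d}" for i in range(1, c.n + 1)]
        roster.extend((tid, c) for tid in ids)
    if len({tid for tid, _ in roster}) != len(roster):
        raise ParameterError("duplicate transcript ids across classes")

    truth = SimTruth()
    expected = np.empty((len(roster), len(t)), dtype=float)
    host_total_end = 0.0
    phage_unscaled_end = 0.0
    for i, (tid, cls) in enumerate(roster):
        rng = np.random.default_rng([cfg.seed, _TRANSCRIPT_STREAM, i])
        rate = cls.amplitude * rng.lognormal(
            mean=0.0, sigma=cfg.abundance_sigma
        )
        if cls.genome == "host":
            shape = _host_shape(t, cfg.host_decay_rate, cfg.host_decay_onset)
            host_total_end += rate * shape[-1]
        else:
            shape = _phage_shape(t, float(cls.tau), cls.slope)
            phage_unscaled_end += rate * shape[-1]
        expected[i] = rate * shape
        truth.transcripts[tid] = TranscriptTruth(
            class_label=cls.label, genome=cls.genome, tau=cls.tau, rate=rate
        )

    # calibrate the phage amplitude to the target end-point share
    s = cfg.target_phage_share_end
    if phage_unscaled_end > 0:
        alpha = (s / (1.0 - s)) * host_total_end / phage_unscaled_end
    else:
        alpha = 0.0
    phage_rows = np.array([c.genome == "phage" for _, c in roster])
    expected[phage_rows] *= alpha

    # library scale: expected total at t0 equals reads_per_timepoint
    base = expected[:, 0].sum()
    if base > 0:
        expected *= cfg.reads_per_timepoint / base

    counts = np.empty_like(expected, dtype=np.int64)
    for i in range(len(roster)):
        rng = np.random.default_rng([cfg.seed, _TRANSCRIPT_STREAM, i, 1])
        counts[i] = rng.poisson(expected[i])

    tc = CountsTimecourse(
        transcript_ids=[tid for tid, _ in roster],
        genome=[c.genome for _, c in roster],
        timepoints=t,
        counts=counts,
    )
    return tc, truth


def planted_binder_ids() -> list[str]:
    """Ids of the planted ribosome-binder proteins in the default gradient
    (shared with the default time course's early-ribosome transcripts, so
    the joint simulation links protein and transcript by identity)."""
    return [f"phage_rib30_{i:03d}" for i in range(1, 4)] + [
        f"phage_rib50_{i:03d}" for i in range(1, 6)
    ]


def default_timecourse_config(seed: int = 42, **overrides) -> TimecourseConfig:
    """The default infection time course: samples every 2 min over 0–10
    min; early phage classes (including the 8 ribosome-binder transcripts)
    switch on before the phage-polymerase class, which precedes the
    structural class; the expected phage share of coding reads reaches 40%
    at 10 min."""
    classes = [
        TimecourseClass(
            "early_ribosome", "phage", 8, tau=3.0, slope=1.5,
            transcript_ids=planted_binder_ids(),
        ),
        TimecourseClass("early_other", "phage", 40, tau=3.5, slope=1.5),
        TimecourseClass("mid_nvRNAP", "phage", 20, tau=6.5, slope=1.5),
        TimecourseClass("late_structural", "phage", 47, tau=9.0, slope=1.5),
        TimecourseClass("host_baseline", "host", 400),
    ]
    return TimecourseConfig(classes=classes, seed=seed, **overrides)


# ---------------------------------------------------------------------------
# recovery metrics (shared by tests, pipeline report and acceptance script)


def assignment_accuracy(assignments, truth: SimTruth) -> float:
    """Fraction of true machinery proteins assigned their true label."""
    want = truth.machinery_proteins()
    got = {a.protein_id: a.label for a in assignments}
    scored = [pid for pid in want if pid in got]
    if not scored:
        raise ParameterError("no machinery proteins among assignments")
    hits = sum(got[pid] == want[pid] for pid in scored)
    return hits / len(scored)


def candidate_recall_precision(
    called_ids: list[str], truth: SimTruth
) -> tuple[float, float]:
    """(recall, precision) of called candidates vs planted binders."""
    planted = set(truth.planted_binders())
    called = set(called_ids)
    if not planted:
        raise ParameterError("no planted binders in truth")
    recall = len(called & planted) / len(planted)
    precision = len(called & planted) / len(called) if called else 0.0
    return recall, precision
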