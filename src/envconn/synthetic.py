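"""Synthetic cohorts of source-level oscillatory recordings with known truth.

Real resting-state MEG source data cannot be redistributed, so every
downstream stage of this package is exercised against simulated cohorts
in which the amplitude-envelope correlation structure is planted and
therefore known exactly.

The generative model, per frequency band:

* Node amplitude envelopes are a lognormal transform of a latent
  Gaussian AR(1) process.  The latent spatial correlation matrix is
  chosen by a Gaussian-copula inversion so that the *envelope* Pearson
  correlations equal the requested target matrix.  The AR(1) time
  constant (default 1 s) gives the slow envelope dynamics that survive
  1 Hz downsampling.
* Each envelope multiplies an independent random-phase narrowband
  carrier (band-limited Gaussian noise), so the Hilbert envelope of the
  result is non-degenerate and carrier phases carry no correlation.
* Band signals are summed per node; an optional zero-lag linear mixing
  operator emulates source leakage.

Group effects are planted as additive increments to the envelope
correlation of chosen (node, node, band) edges in the case group.
Everything is deterministic given the design seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .bands import ALPHA, DEFAULT_BANDS, BandSpec

__all__ = [
    "CohortDesign",
    "SubjectRecording",
    "GroundTruth",
    "simulate_subject",
    "simulate_envelopes",
    "simulate_cohort",
    "simulate_envelope_cohort",
    "mix_leakage",
    "leakage_operator",
]

_PSD_TOL = 1e-8


def default_base_corr(n_nodes: int, rho: float = 0.6, length: float = 3.0) -> np.ndarray:
    """Smooth distance-dependent envelope correlation in node-index space.

    ``corr(i, j) = rho * exp(-|i - j| / length)`` off the diagonal.
    Real amplitude-envelope connectomes have strong, reproducible
    structure — the premise of rank-based edge masking — so simulated
    cohorts carry a stable connectivity gradient rather than flat noise.
    Positive definite for rho < 1 (convex blend of a Kac–Murdock–Szegő
    matrix with the identity).
    """
    idx = np.arange(n_nodes)
    dist = np.abs(idx[:, None] - idx[None, :])
    c = rho * np.exp(-dist / length)
    np.fill_diagonal(c, 1.0)
    return c


@dataclass
class SubjectRecording:
    """One subject's node-by-sample source timeseries."""

    subject_id: str
    group: str  # "case" | "control"
    data: np.ndarray  # (n_nodes, n_samples)
    sampling_rate: float
    node_labels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (nodes x samples) array")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"recording {self.subject_id!r} contains non-finite values")
        if len(self.node_labels) != self.data.shape[0]:
            raise ValueError("node_labels length must match node count")

    @property
    def n_nodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class GroundTruth:
    """Planted effects and seed bookkeeping for a simulated cohort."""

    effect_edges: list[tuple[int, int, str]]
    effect_size: float
    subject_seeds: dict[str, int]


@dataclass
class CohortDesign:
    """Full description of a simulated two-group cohort.

    ``base_envelope_corr`` maps band name to the target envelope
    correlation matrix for that band (identity if omitted).  In the case
    group, ``effect_size`` is added to the envelope correlation of every
    ``(i, j, band)`` in ``effect_edges``.
    """

    n_case: int
    n_control: int
    n_nodes: int = 90
    duration: float = 300.0  # seconds
    sampling_rate: float = 600.0  # Hz
    bands: Sequence[BandSpec] = DEFAULT_BANDS
    base_envelope_corr: Mapping[str, np.ndarray] | None = None
    effect_edges: Sequence[tuple[int, int, str]] = ()
    effect_size: float = 0.0
    leakage_strength: float = 0.0
    seed: int = 0
    envelope_sigma: float = 1.0  # lognormal modulation depth
    envelope_tau: float = 1.0  # envelope autocorrelation time, s

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError(
                f"both groups must be non-empty (got n_case={self.n_case}, "
                f"n_control={self.n_control})"
            )
        if not 0 <= self.leakage_strength < 1:
            raise ValueError("leakage_strength must lie in [0, 1)")
        for band in self.bands:
            band.check_nyquist(self.sampling_rate)
        names = [b.name for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("band names must be unique")
        for i, j, bname in self.effect_edges:
            if bname not in names:
                raise ValueError(f"effect edge references unknown band {bname!r}")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes) or i == j:
                raise ValueError(f"effect edge ({i}, {j}) is not a valid node pair")
        # Target matrices (case and control) must be valid correlation
        # matrices; checked eagerly so errors name the offending band.
        for band in self.bands:
            for group in ("control", "case"):
                self.target_corr(band.name, group)

    def base_corr(self, band_name: str) -> np.ndarray:
        if self.base_envelope_corr and band_name in self.base_envelope_corr:
            c = np.asarray(self.base_envelope_corr[band_name], dtype=float)
        else:
            c = default_base_corr(self.n_nodes)
        if c.shape != (self.n_nodes, self.n_nodes):
            raise ValueError(
                f"base correlation for band {band_name!r} has shape {c.shape}, "
                f"expected ({self.n_nodes}, {self.n_nodes})"
            )
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError(f"base correlation for band {band_name!r} is not symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-12):
            raise ValueError(f"base correlation for band {band_name!r} has non-unit diagonal")
        return c

    def target_corr(self, band_name: str, group: str) -> np.ndarray:
        """Envelope correlation target for one band and group; PSD-checked."""
        if group not in ("case", "control"):
            raise ValueError(f"group must be 'case' or 'control', got {group!r}")
        c = self.base_corr(band_name).copy()
        if group == "case":
            for i, j, bname in self.effect_edges:
                if bname == band_name:
                    c[i, j] += self.effect_size
                    c[j, i] += self.effect_size
        lam_min = float(np.linalg.eigvalsh(c).min())
        if lam_min < -_PSD_TOL:
            raise ValueError(
                f"target envelope correlation for band {band_name!r} ({group}) is "
                f"not positive semidefinite (min eigenvalue {lam_min:.3g}); reduce "
                "effect_size or adjust base_envelope_corr"
            )
        return c

    @property
    def n_subjects(self) -> int:
        return self.n_case + self.n_control

    @property
    def node_labels(self) -> list[str]:
        return [f"node{k:03d}" for k in range(self.n_nodes)]


def _latent_corr(env_corr: np.ndarray, sigma: float, band_name: str) -> np.ndarray:
    """Gaussian-copula inversion: latent correlation giving lognormal
    envelopes whose Pearson correlation equals ``env_corr``."""
    s2 = sigma**2
    arg = 1.0 + env_corr * math.expm1(s2)
    if np.any(arg <= 0):
        raise ValueError(
            f"band {band_name!r}: envelope correlation too negative for "
            f"lognormal model at sigma={sigma} (needs r > {-1 / math.expm1(s2):.3f})"
        )
    lat = np.log(arg) / s2
    np.fill_diagonal(lat, 1.0)
    lam_min = float(np.linalg.eigvalsh(lat).min())
    if lam_min < -_PSD_TOL:
        raise ValueError(
            f"band {band_name!r}: latent (copula) correlation matrix is not "
            f"positive semidefinite (min eigenvalue {lam_min:.3g})"
        )
    return lat


def _corr_sqrt(c: np.ndarray) -> np.ndarray:
    """Symmetric square root with clipping of numerically-negative modes."""
    lam, v = np.linalg.eigh(c)
    lam = np.clip(lam, 0.0, None)
    return v * np.sqrt(lam)


def _correlated_lognormal(
    env_corr: np.ndarray,
    n_samples: int,
    rate: float,
    sigma: float,
    tau: float,
    rng: np.random.Generator,
    band_name: str,
) -> np.ndarray:
    """Stationary positive envelopes (nodes x samples) at sampling ``rate``
    whose pairwise Pearson correlations equal ``env_corr``."""
    lat = _latent_corr(env_corr, sigma, band_name)
    mix = _corr_sqrt(lat)
    n_nodes = env_corr.shape[0]
    phi = math.exp(-1.0 / (rate * tau))
    innov = mix @ rng.standard_normal((n_nodes, n_samples))
    x0 = mix @ rng.standard_normal(n_nodes)
    # AR(1) with stationary initial state: unit marginal variance throughout.
    zi = (phi * x0)[:, None]
    x, _ = lfilter([math.sqrt(1 - phi**2)], [1.0, -phi], innov, axis=1, zi=zi)
    return np.exp(sigma * x - 0.5 * sigma**2)


def _narrowband_carrier(
    band: BandSpec, n_nodes: int, n_samples: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Independent unit-variance random-phase band-limited noise per node."""
    white = rng.standard_normal((n_nodes, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    spec[:, (freqs < band.f_low) | (freqs > band.f_high)] = 0.0
    carrier = np.fft.irfft(spec, n=n_samples, axis=1)
    sd = carrier.std(axis=1, ddof=0, keepdims=True)
    if np.any(sd == 0):
        raise ValueError(f"band {band.name!r}: no spectral support at rate {rate} Hz")
    return carrier / sd


def simulate_envelopes(
    design: CohortDesign,
    group: str,
    subject_seed: int,
    rate: float | None = None,
    n_samples: int | None = None,
) -> dict[str, np.ndarray]:
    """Per-band node envelopes for one subject, without carriers.

    By default, samples at 1 Hz with length ``floor(duration) - 5`` —
    i.e. directly at the grid the conditioned envelope pipeline delivers
    — which makes envelope-level cohorts cheap for statistical studies
    that do not need the raw timeseries.
    """
    if rate is None:
        rate = 1.0
    if n_samples is None:
        n_samples = int(math.floor(design.duration)) - 5
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    out: dict[str, np.ndarray] = {}
    for k, band in enumerate(design.bands):
        rng = np.random.default_rng([abs(int(design.seed)), int(subject_seed), k])
        c = design.target_corr(band.name, group)
        out[band.name] = _correlated_lognormal(
            c, n_samples, rate, design.envelope_sigma, design.envelope_tau, rng, band.name
        )
    return out


def simulate_subject(
    design: CohortDesign, group: str, subject_seed: int, subject_id: str | None = None
) -> SubjectRecording:
    """Simulate one subject's broadband node timeseries.

    Per band, correlated envelopes modulate independent narrowband
    carriers; bands are summed per node, then leakage mixing is applied
    if the design requests it.  Deterministic in
    ``(design.seed, subject_seed)``.
    """
    if group not in ("case", "control"):
        raise ValueError(f"group must be 'case' or 'control', got {group!r}")
    n = int(round(design.duration * design.sampling_rate))
    data = np.zeros((design.n_nodes, n))
    for k, band in enumerate(design.bands):
        rng = np.random.default_rng([abs(int(design.seed)), int(subject_seed), k])
        c = design.target_corr(band.name, group)
        env = _correlated_lognormal(
            c, n, design.sampling_rate, design.envelope_sigma, design.envelope_tau,
            rng, band.name,
        )
        carrier = _narrowband_carrier(band, design.n_nodes, n, design.sampling_rate, rng)
        data += env * carrier
    rec = SubjectRecording(
        subject_id=subject_id or f"{group}_{subject_seed:04d}",
        group=group,
        data=data,
        sampling_rate=design.sampling_rate,
        node_labels=design.node_labels,
        metadata={"design_seed": design.seed, "subject_seed": subject_seed},
    )
    if design.leakage_strength > 0:
        rec = mix_leakage(rec, design.leakage_strength)
    return rec


def leakage_operator(n_nodes: int, strength: float) -> np.ndarray:
    """Row-stochastic nearest-neighbour blend in node-index space.

    Each node keeps weight ``1 - strength`` and spreads ``strength``
    equally over its index neighbours; ``strength = 0`` is the identity.
    The operator creates zero-lag cross-talk analogous to source
    leakage, without any forward model.
    """
    if not 0 <= strength < 1:
        raise ValueError(f"leakage strength must lie in [0, 1), got {strength}")
    m = np.eye(n_nodes) * (1.0 - strength)
    for i in range(n_nodes):
        nbrs = [j for j in (i - 1, i + 1) if 0 <= j < n_nodes]
        for j in nbrs:
            m[i, j] += strength / len(nbrs)
    return m


def mix_leakage(recording: SubjectRecording, strength: float) -> SubjectRecording:
    """Blend each node's timeseries with its neighbours (zero-lag mixing)."""
    m = leakage_operator(recording.n_nodes, strength)
    meta = dict(recording.metadata)
    meta["leakage_strength"] = strength
    return SubjectRecording(
        subject_id=recording.subject_id,
        group=recording.group,
        data=m @ recording.data,
        sampling_rate=recording.sampling_rate,
        node_labels=list(recording.node_labels),
        metadata=meta,
    )


def _cohort_roster(design: CohortDesign) -> list[tuple[str, str, int]]:
    """(subject_id, group, subject_seed) triples; seeds are the cohort index."""
    roster = []
    for k in range(design.n_case):
        roster.append((f"case_{k:04d}", "case", k))
    for k in range(design.n_control):
        roster.append((f"control_{k:04d}", "control", design.n_case + k))
    return roster


def simulate_cohort(design: CohortDesign) -> tuple[list[SubjectRecording], GroundTruth]:
    """Simulate all subjects of a two-group cohort.

    Per-subject seeds are the subject's cohort index, combined with the
    design seed inside :func:`simulate_subject`, so the whole cohort is
    reproducible from ``design.seed`` alone.
    """
    roster = _cohort_roster(design)
    recordings = [
        simulate_subject(design, group, seed, subject_id=sid)
        for sid, group, seed in roster
    ]
    truth = GroundTruth(
        effect_edges=[(min(i, j), max(i, j), b) for i, j, b in design.effect_edges],
        effect_size=design.effect_size,
        subject_seeds={sid: seed for sid, _, seed in roster},
    )
    return recordings, truth


def simulate_envelope_cohort(design: CohortDesign):
    """Envelope-level cohort: conditioned 1 Hz envelopes per subject/band.

    Skips carrier synthesis and the raw-signal pipeline entirely —
    appropriate for statistical studies (null calibration, mask
    behaviour) where the quantity of interest lives at the envelope
    level.  Returns ``(subjects, env_sets, truth)`` where ``subjects``
    is a list of ``(subject_id, group)`` and ``env_sets`` maps band name
    to a list of :class:`~envconn.envelope.EnvelopeSet` aligned with
    ``subjects``.
    """
    from .envelope import EnvelopeSet  # deferred: avoids an import cycle

    roster = _cohort_roster(design)
    env_sets: dict[str, list] = {b.name: [] for b in design.bands}
    for sid, group, seed in roster:
        envs = simulate_envelopes(design, group, seed)
        for band in design.bands:
            env_sets[band.name].append(
                EnvelopeSet(subject_id=sid, band=band, env=envs[band.name], rate=1.0)
            )
    truth = GroundTruth(
        effect_edges=[(min(i, j), max(i, j), b) for i, j, b in design.effect_edges],
        effect_size=design.effect_size,
        subject_seeds={sid: seed for sid, _, seed in roster},
    )
    subjects = [(sid, group) for sid, group, _ in roster]
    return subjects, env_sets, truth
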