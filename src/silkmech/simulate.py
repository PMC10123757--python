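"""Phenomenological cyclic-test generator for a supercontracted silk fiber.

The generator emits machine records (time, displacement, force) of a
35-cycle loading-unloading test with known ground truth, so the whole
analysis pipeline can be exercised and validated without laboratory data.
It is calibrated to the headline behaviour of maximum-supercontracted
major ampullate silk: reloading modulus growing from ~3 to ~12 GPa,
near-constant yield stress (~120 to ~140 MPa), strong hysteresis with
partial strain recovery during the holds between cycles, and a
history-independent envelope whose integral (work to fracture) is
270 MJ/m^3.

Model
-----
Envelope (master curve, true coordinates)::

    sigma_env(eps) = E1 * eps                          for eps <= eps_y
    sigma_env(eps) = sigma_y1 + K * (eps - eps_y)**n   for eps >  eps_y

with ``eps_y = sigma_y1 / E1``.  The hardening coefficient ``K`` is
derived in closed form so that the envelope integral up to the final
strain equals the target work to fracture.

Cycle ``k`` (1-based) loads from its residual strain ``eps_r_k`` at
modulus ``E_k`` up to the scheduled yield stress, crosses over to the
envelope at the previous maximum strain ``eps_h_k = (k-1)*d_eps`` via a
monotone S-shaped knee, and follows the envelope up to
``eps_max_k = k*d_eps``.  Unloading is a power law ending at
``eps_u_k``; during the hold the fiber recovers a fraction ``rho`` of
the strain accumulated in the cycle:

    eps_u_k   = max(eps_r_k, eps_max_k - c_e * sigma_max_k / E_k)
    eps_r_k+1 = eps_u_k - rho * (eps_u_k - eps_r_k)

The modulus schedule is linear in the residual (onset) strain,
``E_k = E1 + (EN - E1) * eps_r_k / eps_r_N``; because ``eps_u_k`` itself
depends on ``E_k`` the schedule and the recursion are solved together by
fixed-point iteration.  The yield schedule is linear in the cycle index.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, GenerationError
from .kinematics import EngCurve, TrueCurve, engineering_from_true, record_from_engineering
from .records import FiberGeometry, TensileRecord, write_geometry

__all__ = ["FiberModelParams", "GroundTruth", "EnvelopeModel", "envelope_model", "generate_test", "write_fixture_suite"]


def _default_geometry() -> FiberGeometry:
    # plausible MAS values: 5 um forcibly-silked diameter, 25 mm -> 20 mm supercontraction
    return FiberGeometry.from_diameter(5.0, 25.0, 20.0)


@dataclass(frozen=True)
class FiberModelParams:
    """Parameters of the phenomenological fiber model.

    Defaults reproduce the study conditions: 35 cycles of 0.025
    true-strain increments at 0.5/min on a maximum-supercontracted fiber
    with E 3 -> 12 GPa, yield 120 -> 140 MPa and a 270 MJ/m^3 envelope.
    """

    e1: float = 3000.0                 # first-cycle modulus, MPa
    en: float = 12000.0                # last-cycle modulus, MPa
    sigma_y1: float = 120.0            # first-cycle yield, MPa
    sigma_yn: float = 140.0            # last-cycle yield, MPa
    n_cycles: int = 35
    d_eps: float = 0.025               # true-strain increment per cycle
    hardening_exponent: float = 1.5
    work_to_fracture: float = 270.0    # envelope integral target, MJ/m^3; fixes K
    unload_shape: float = 2.0          # power-law exponent m of the unloading branch
    elastic_recovery_factor: float = 1.2   # c_e: unloading strain span = c_e*sigma_max/E
    relax_recovery_fraction: float = 0.3   # rho: strain fraction recovered in the hold
    calibration_strain: float = 0.875  # strain at which the envelope integral equals W_f
    noise_sd: float = 0.0              # Gaussian true-stress noise, MPa
    seed: int = 0
    strain_rate: float = 0.5           # 1/min (true strain)
    hold_s: float = 1200.0             # 20-min relaxation hold between cycles
    sample_deps: float = 2e-4          # strain step between samples on active branches
    slack_deps: float = 2e-3           # coarser strain step on zero-load travel
    geometry: FiberGeometry = field(default_factory=_default_geometry)

    def __post_init__(self):
        if self.e1 > self.en:
            raise DomainError("E1 must not exceed EN")
        if self.sigma_y1 > self.sigma_yn:
            raise DomainError("sigma_y1 must not exceed sigma_yN")
        if not 0.0 <= self.relax_recovery_fraction <= 1.0:
            raise DomainError("relax_recovery_fraction must lie in [0, 1]")
        if self.unload_shape < 1.0:
            raise DomainError("unload_shape must be >= 1")
        if self.n_cycles < 1 or self.d_eps <= 0:
            raise DomainError("need n_cycles >= 1 and d_eps > 0")

    @property
    def eps_final(self) -> float:
        return self.n_cycles * self.d_eps

    @property
    def eps_yield_envelope(self) -> float:
        return self.sigma_y1 / self.e1

    @property
    def hardening_coefficient(self) -> float:
        """K (MPa), derived so the envelope integral up to the calibration
        strain equals the target W_f.

        Closed form of the integral to a strain L:
        ``0.5*E1*eps_y**2 + sigma_y1*(L - eps_y) + K*(L - eps_y)**(n+1)/(n+1)``.
        The calibration strain is the full-length test extent, so truncating
        a test (fewer cycles) keeps the same master curve.
        """
        eps_y = self.eps_yield_envelope
        span = self.calibration_strain - eps_y
        if span <= 0:
            # the test never leaves the elastic branch; hardening is moot
            return 0.0
        n = self.hardening_exponent
        elastic = 0.5 * self.e1 * eps_y**2
        plateau = self.sigma_y1 * span
        k = (self.work_to_fracture - elastic - plateau) * (n + 1.0) / span ** (n + 1.0)
        if k <= 0:
            raise DomainError("work-to-fracture target too small for a positive hardening coefficient")
        return k


class EnvelopeModel:
    """Callable analytic envelope with derivative and closed-form integral."""

    def __init__(self, params: FiberModelParams):
        self.params = params
        self.eps_y = params.eps_yield_envelope
        self.k = params.hardening_coefficient
        self.n = params.hardening_exponent

    def __call__(self, eps):
        eps = np.asarray(eps, dtype=float)
        if np.any(eps < -1e-12) or np.any(eps > self.params.eps_final + 1e-12):
            raise DomainError("envelope strain outside [0, final strain]")
        post = np.clip(eps - self.eps_y, 0.0, None)
        out = np.where(eps <= self.eps_y, self.params.e1 * eps, self.params.sigma_y1 + self.k * post**self.n)
        return out if out.ndim else float(out)

    def derivative(self, eps):
        eps = np.asarray(eps, dtype=float)
        post = np.clip(eps - self.eps_y, 1e-300, None)
        out = np.where(eps <= self.eps_y, self.params.e1, self.k * self.n * post ** (self.n - 1.0))
        return out if out.ndim else float(out)

    def integral(self, upper: float) -> float:
        """Closed-form integral of the envelope from 0 to ``upper`` (MJ/m^3)."""
        p = self.params
        if upper <= self.eps_y:
            return 0.5 * p.e1 * upper**2
        span = upper - self.eps_y
        return 0.5 * p.e1 * self.eps_y**2 + p.sigma_y1 * span + self.k * span ** (self.n + 1.0) / (self.n + 1.0)


def envelope_model(params: FiberModelParams) -> EnvelopeModel:
    """Build the analytic envelope for a parameter set."""
    return EnvelopeModel(params)


@dataclass
class GroundTruth:
    """Per-cycle generator state and analytic envelope values."""

    modulus: np.ndarray          # E_k, MPa
    yield_schedule: np.ndarray   # scheduled sigma_y_k, MPa
    eps_residual: np.ndarray     # onset strain eps_r_k of each cycle
    eps_unload: np.ndarray       # strain at which each unloading reaches zero stress
    eps_max: np.ndarray          # k * d_eps
    sigma_max: np.ndarray        # envelope stress at eps_max
    envelope_strain: np.ndarray  # fine-grid envelope knots
    envelope_stress: np.ndarray
    envelope_integral: float     # closed form, MJ/m^3
    hardening_coefficient: float

    def to_dict(self) -> dict:
        return {
            "modulus_MPa": self.modulus.tolist(),
            "yield_schedule_MPa": self.yield_schedule.tolist(),
            "eps_residual": self.eps_residual.tolist(),
            "eps_unload": self.eps_unload.tolist(),
            "eps_max": self.eps_max.tolist(),
            "sigma_max_MPa": self.sigma_max.tolist(),
            "envelope_integral_MJm3": self.envelope_integral,
            "hardening_coefficient_MPa": self.hardening_coefficient,
        }


def _schedules(params: FiberModelParams, env: EnvelopeModel):
    """Solve the modulus schedule / residual-strain recursion fixed point."""
    n = params.n_cycles
    eps_max = params.d_eps * np.arange(1, n + 1)
    sigma_max = np.asarray(env(eps_max), dtype=float).reshape(-1)
    rho = params.relax_recovery_fraction
    ce = params.elastic_recovery_factor

    if n == 1:
        moduli = np.array([params.e1])
    else:
        moduli = params.e1 + (params.en - params.e1) * np.arange(n) / (n - 1)
    eps_r = np.zeros(n)
    eps_u = np.zeros(n)
    for _ in range(200):
        for k in range(n):
            eps_u[k] = max(eps_r[k], eps_max[k] - ce * sigma_max[k] / moduli[k])
            if k + 1 < n:
                eps_r[k + 1] = eps_u[k] - rho * (eps_u[k] - eps_r[k])
        if eps_r[-1] <= 0:
            new = np.full(n, params.e1)
        else:
            new = params.e1 + (params.en - params.e1) * eps_r / eps_r[-1]
        if np.max(np.abs(new - moduli)) < 1e-10:
            moduli = new
            break
        moduli = new
    # recompute the recursion once more with the converged schedule
    for k in range(n):
        eps_u[k] = max(eps_r[k], eps_max[k] - ce * sigma_max[k] / moduli[k])
        if k + 1 < n:
            eps_r[k + 1] = eps_u[k] - rho * (eps_u[k] - eps_r[k])

    if n == 1:
        sigma_y = np.array([params.sigma_y1])
    else:
        sigma_y = params.sigma_y1 + (params.sigma_yn - params.sigma_y1) * np.arange(n) / (n - 1)
    return eps_max, sigma_max, moduli, sigma_y, eps_r, eps_u


def _loading_profile(params: FiberModelParams, env: EnvelopeModel, k: int,
                     eps_r: float, eps_h: float, eps_max: float,
                     modulus: float, sig_y: float, plateau_fraction: float = 0.35):
    """Return sigma(eps) for the loading branch of 1-based cycle ``k``.

    Cycle 1 loads along the envelope.  Later cycles follow the elastic
    line from (eps_r, 0); if the line meets the envelope below the
    scheduled yield stress the branch is min(line, envelope), otherwise
    an S-shaped knee (low-slope plateau + monotone cubic stiffening
    segment) carries it to the envelope at eps_h with matching slope.
    """
    if k == 1:
        return lambda eps: np.asarray(env(eps), dtype=float)

    def line(eps):
        return modulus * (np.asarray(eps, dtype=float) - eps_r)

    def gap(eps):
        return float(line(eps) - env(eps))

    eps_yk = eps_r + sig_y / modulus
    sig_h = float(env(eps_h))
    feasible_knee = eps_yk < eps_h and sig_y < sig_h

    grid = np.linspace(eps_r, eps_max, 513)[1:]
    gaps = line(grid) - np.asarray(env(grid), dtype=float)

    def min_line_env(eps):
        eps = np.asarray(eps, dtype=float)
        return np.minimum(line(eps), np.asarray(env(eps), dtype=float))

    if gaps[-1] >= 0:
        # the elastic line reaches the envelope; eps_x is where it last comes
        # up from below (gap >= 0 is a tail interval: line linear, env convex)
        neg = np.flatnonzero(gaps < 0)
        if len(neg) == 0:
            eps_x = float(grid[0])
        elif neg[-1] == len(grid) - 1:
            eps_x = None
        else:
            i = int(neg[-1])
            eps_x = float(brentq(gap, float(grid[i]), float(grid[i + 1]), xtol=1e-12))
        if eps_x is not None and eps_x <= eps_yk:
            # line meets the envelope below the scheduled yield: follow
            # the line, then the envelope
            if eps_x > eps_h + 1e-9:
                raise GenerationError(
                    "elastic line meets the envelope beyond the previous maximum strain", cycle=k
                )
            return min_line_env
        if not feasible_knee:
            raise GenerationError("no monotone loading path to the envelope", cycle=k)
    else:
        # the line never reaches the envelope within the cycle
        if not feasible_knee:
            # a virgin-like cycle (zero residual strain, first-cycle
            # modulus) simply retraces the envelope
            elastic = grid[grid <= min(eps_h, env.eps_y)]
            rides = len(elastic) and np.max(np.abs(line(elastic) - np.asarray(env(elastic), dtype=float))) <= 1e-6 * sig_h
            if rides:
                return lambda eps: np.asarray(env(eps), dtype=float)
            raise GenerationError("elastic line cannot reach the envelope", cycle=k)

    # S-shaped knee: plateau then monotone cubic Hermite join to the envelope
    span = eps_h - eps_yk
    secant = (sig_h - sig_y) / span
    m2 = float(env.derivative(eps_h))
    c0 = min(m2, 0.5 * secant)
    lam = plateau_fraction * span
    eps_p = eps_yk + lam
    sig_p = sig_y + c0 * lam
    span2 = eps_h - eps_p
    delta2 = (sig_h - sig_p) / span2
    # Fritsch-Carlson: alpha^2 + beta^2 <= 9 guarantees a monotone cubic
    alpha, beta = c0 / delta2, m2 / delta2
    if alpha * alpha + beta * beta > 9.0:
        raise GenerationError("stiffening segment would be non-monotone", cycle=k)

    def cubic(eps):
        t = (np.asarray(eps, dtype=float) - eps_p) / span2
        h00 = 2 * t**3 - 3 * t**2 + 1
        h10 = t**3 - 2 * t**2 + t
        h01 = -2 * t**3 + 3 * t**2
        h11 = t**3 - t**2
        return h00 * sig_p + h10 * span2 * c0 + h01 * sig_h + h11 * span2 * m2

    def sigma(eps):
        eps = np.asarray(eps, dtype=float)
        out = np.empty_like(eps)
        m_el = eps <= eps_yk
        m_pl = (eps > eps_yk) & (eps <= eps_p)
        m_cu = (eps > eps_p) & (eps < eps_h)
        m_en = eps >= eps_h
        out[m_el] = line(eps[m_el])
        out[m_pl] = sig_y + c0 * (eps[m_pl] - eps_yk)
        out[m_cu] = cubic(eps[m_cu])
        out[m_en] = np.asarray(env(eps[m_en]), dtype=float)
        return out

    return sigma


def _sample_span(lo: float, hi: float, step: float) -> np.ndarray:
    """Inclusive linspace from lo to hi with spacing <= step (>= 2 points)."""
    if hi <= lo:
        return np.array([lo])
    n = max(2, int(np.ceil((hi - lo) / step)) + 1)
    return np.linspace(lo, hi, n)


def generate_test(params: FiberModelParams) -> tuple[TensileRecord, GroundTruth]:
    """Generate one cyclic tensile test as a machine record plus ground truth.

    The true-strain path is sampled at constant true-strain rate; slack
    travel (crosshead moving while the fiber carries no load) is sampled
    more coarsely at exactly zero stress, and the 20-min relaxation holds
    appear as time gaps at the gauge position.  Optional Gaussian stress
    noise (seeded) perturbs the force channel only.
    """
    env = EnvelopeModel(params)
    eps_max, sigma_max, moduli, sigma_y, eps_r, eps_u = _schedules(params, env)
    n = params.n_cycles

    strain_parts: list[np.ndarray] = []
    stress_parts: list[np.ndarray] = []
    dt_extra: list[float] = []  # per-part extra time inserted before the part
    rate_s = params.strain_rate / 60.0  # 1/s

    for k in range(n):
        eps_h = k * params.d_eps  # previous cycle maximum (0 for cycle 1)
        profile = _loading_profile(
            params, env, k + 1, float(eps_r[k]), eps_h, float(eps_max[k]),
            float(moduli[k]), float(sigma_y[k]),
        )
        # slack approach from the gauge position to the residual strain
        if eps_r[k] > 0:
            slack = _sample_span(0.0, float(eps_r[k]), params.slack_deps)[:-1]
            strain_parts.append(slack)
            stress_parts.append(np.zeros_like(slack))
            dt_extra.append(0.0)
        load = _sample_span(float(eps_r[k]), float(eps_max[k]), params.sample_deps)
        strain_parts.append(load)
        stress_parts.append(np.asarray(profile(load), dtype=float))
        dt_extra.append(0.0)

        span_u = float(eps_max[k] - eps_u[k])
        if span_u <= 0:
            raise GenerationError("degenerate unloading span", cycle=k + 1)
        unload = _sample_span(float(eps_u[k]), float(eps_max[k]), params.sample_deps)[::-1][1:]
        x = (unload - eps_u[k]) / span_u
        strain_parts.append(unload)
        stress_parts.append(sigma_max[k] * np.clip(x, 0.0, None) ** params.unload_shape)
        dt_extra.append(0.0)
        # slack return to the gauge position, then the relaxation hold
        back = _sample_span(0.0, float(eps_u[k]), params.slack_deps)[::-1][1:]
        strain_parts.append(back)
        stress_parts.append(np.zeros_like(back))
        dt_extra.append(0.0)
        if k + 1 < n:
            strain_parts.append(np.array([0.0]))
            stress_parts.append(np.array([0.0]))
            dt_extra.append(params.hold_s)

    strain = np.concatenate(strain_parts)
    stress = np.concatenate(stress_parts)
    # time base: constant true-strain rate plus the inserted holds; a 1 ms
    # tick floor keeps time strictly increasing across repeated positions
    dt = np.maximum(np.abs(np.diff(strain)) / rate_s, 1e-3)
    offsets = np.zeros(len(strain))
    pos = 0
    for part, extra in zip(strain_parts, dt_extra):
        if extra:
            offsets[pos] += extra
        pos += len(part)
    time = np.concatenate([[0.0], np.cumsum(dt)])
    time += np.cumsum(offsets)

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        stress = stress + rng.normal(0.0, params.noise_sd, size=len(stress))

    true_curve = TrueCurve(strain, stress, time=time, sample_id=f"synthetic-seed{params.seed}")
    eng = engineering_from_true(true_curve)
    record = record_from_engineering(eng, params.geometry, sample_id=true_curve.sample_id)

    grid = np.linspace(0.0, params.eps_final, 2001)
    truth = GroundTruth(
        modulus=moduli,
        yield_schedule=sigma_y,
        eps_residual=eps_r,
        eps_unload=eps_u,
        eps_max=eps_max,
        sigma_max=sigma_max,
        envelope_strain=grid,
        envelope_stress=np.asarray(env(grid), dtype=float),
        envelope_integral=env.integral(params.eps_final),
        hardening_coefficient=env.k,
    )
    return record, truth


def write_fixture_suite(directory, seeds, *, noise_sd: float = 2.0, params: FiberModelParams | None = None) -> dict:
    """Write noiseless + noisy records, geometry sidecars and ground truth.

    Returns (and writes) a manifest with SHA-256 checksums of every file.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = params or FiberModelParams()
    manifest: dict = {"files": {}}
    for seed in seeds:
        for label, sd in (("noiseless", 0.0), ("noisy", noise_sd)):
            p = replace(base, seed=int(seed), noise_sd=sd)
            record, truth = generate_test(p)
            rec_path = directory / f"record_seed{seed}_{label}.csv"
            truth_path = directory / f"truth_seed{seed}_{label}.json"
            record.write(rec_path)
            with open(truth_path, "w") as fh:
                json.dump(truth.to_dict(), fh, indent=1)
            for path in (rec_path, truth_path):
                manifest["files"][path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    geo_path = directory / "geometry.yaml"
    write_geometry(base.geometry, geo_path)
    manifest["files"][geo_path.name] = hashlib.sha256(geo_path.read_bytes()).hexdigest()
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
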