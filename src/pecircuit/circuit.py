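"""The eight-unit mean-field prediction-error microcircuit.

Units, in order: nE, pE (somata of the negative/positive PE neurons), nD, pD
(their dendritic compartments), PV1, PV2 (parvalbumin interneurons targeting
the somata), SOM (somatostatin interneuron targeting the dendrites) and VIP.
The rates obey

    T_c dh/dt = -h + W r + w_fb * prediction + w_ff * stimulus + I_bg,
    r = [h]_+,

with tau_E = 60 ms for excitatory entries (somata and dendrites) and
tau_I = 2 ms for interneurons.  Feedforward/feedback routing is complementary
(``w_ff = 1 - w_fb``); the three mean-field network (MFN) variants differ only
in whether the SOM and VIP neurons receive the stimulus or the prediction.

The intra-circuit weights are not free parameters: they are solved from the
multi-pathway excitation/inhibition balance conditions so that (i) a fully
predicted stimulus leaves both PE somata at their zero baseline for any input
level, and (ii) mismatches evoke one-sided responses with finite positive
gain (nE for over-predicted, pE for under-predicted inputs).  See
:func:`build_mfn`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "UNITS",
    "PECircuitParams",
    "CircuitState",
    "PerturbationSpec",
    "LinearFit",
    "PEValidationReport",
    "CircuitBuildError",
    "build_mfn",
    "calibrate_background",
    "step_circuit",
    "simulate_circuit",
    "verify_pe_responses",
    "measure_gains",
    "fit_baseline_gain",
]

UNITS = ("nE", "pE", "nD", "pD", "PV1", "PV2", "SOM", "VIP")
N_UNITS = 8
_E = slice(0, 4)       # excitatory compartments
_I = slice(4, 8)       # interneurons
TAU_E_MS = 60.0
TAU_I_MS = 2.0

# Baseline firing-rate targets of the calibration: PE somata and dendrites
# silent, interneurons at 4 /s.
DEFAULT_BASELINES = np.array([0.0, 0.0, 0.0, 0.0, 4.0, 4.0, 4.0, 4.0])

# Fixed template constants of the balance solve (see build_mfn).
_W_SOM_VIP = 0.5    # SOM <-> VIP mutual inhibition
_W_I_TO_PV = 0.05   # SOM -> PV and VIP -> PV inhibition

# Per-variant free choices inside the feasible cone of the balance
# constraints: the mismatch response coefficient of each PE soma and the
# SOM weight onto each dendrite.  The dendro-somatic couplings are not free:
# they are pinned by the neuromodulation-neutrality constraint (see
# build_mfn).  gamma_n must clear the far-field safety bound checked there.
_TEMPLATE = {
    "MFN1": dict(gamma_n=0.55, gamma_p=0.55, w_nd_som=0.3, w_pd_som=0.3),
    "MFN2": dict(gamma_n=1.0 / 3.0, gamma_p=1.0 / 3.0, w_nd_som=0.3, w_pd_som=0.3),
    "MFN3": dict(gamma_n=0.3, gamma_p=0.3, w_nd_som=0.3, w_pd_som=0.3),
}

# Which units receive the prediction (feedback) in each variant; everyone
# else receives the feedforward input.  Dendrites and PV2 are always
# feedback-targeted; somata and PV1 always feedforward-targeted.
_FB_ROUTING = {
    "MFN1": ("nD", "pD", "PV2", "VIP"),
    "MFN2": ("nD", "pD", "PV2", "SOM"),
    "MFN3": ("nD", "pD", "PV2"),
}


class CircuitBuildError(RuntimeError):
    """Raised when the balance solve cannot produce a validated circuit."""


@dataclass
class PECircuitParams:
    """Connectivity, input routing, background input and time constants."""

    W: np.ndarray                    # (8, 8) intra-circuit weights
    w_ff: np.ndarray                 # (8,) feedforward routing in {0, 1}
    w_fb: np.ndarray                 # (8,) feedback routing in {0, 1}
    I_bg: np.ndarray                 # (8,) background input
    tau: np.ndarray = field(default_factory=lambda: np.array(
        [TAU_E_MS] * 4 + [TAU_I_MS] * 4))
    variant: str = "MFN1"

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, float)
        self.w_ff = np.asarray(self.w_ff, float)
        self.w_fb = np.asarray(self.w_fb, float)
        self.I_bg = np.asarray(self.I_bg, float)
        self.tau = np.asarray(self.tau, float)
        self.validate_structure()

    def validate_structure(self) -> None:
        if self.W.shape != (N_UNITS, N_UNITS):
            raise ValueError("W must be 8x8")
        if not np.allclose(self.w_ff + self.w_fb, 1.0):
            raise ValueError("routing must satisfy w_ff = 1 - w_fb")
        if np.any(self.tau <= 0):
            raise ValueError("time constants must be positive")
        # Dale's sign pattern: columns from excitatory units non-negative,
        # from interneurons non-positive.
        if np.any(self.W[:, _E] < 0):
            raise ValueError("excitatory outgoing weights must be >= 0")
        if np.any(self.W[:, _I] > 0):
            raise ValueError("inhibitory outgoing weights must be <= 0")
        # Compartment targeting: SOM inhibits dendrites only, PV somata only.
        som = UNITS.index("SOM")
        for pv in (UNITS.index("PV1"), UNITS.index("PV2")):
            if np.any(self.W[2:4, pv] != 0):
                raise ValueError("PV must not target dendrites")
        if np.any(self.W[0:2, som] != 0):
            raise ValueError("SOM must not target somata")

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "W": self.W.tolist(),
            "w_ff": self.w_ff.tolist(),
            "w_fb": self.w_fb.tolist(),
            "I_bg": self.I_bg.tolist(),
            "tau": self.tau.tolist(),
            "units": list(UNITS),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d: dict) -> "PECircuitParams":
        return cls(W=np.array(d["W"]), w_ff=np.array(d["w_ff"]),
                   w_fb=np.array(d["w_fb"]), I_bg=np.array(d["I_bg"]),
                   tau=np.array(d["tau"]), variant=d.get("variant", "MFN1"))

    @classmethod
    def from_json(cls, path: str | Path) -> "PECircuitParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CircuitState:
    """Pre-rectification variables ``h`` and rates ``r = [h]_+``."""

    h: np.ndarray

    @property
    def r(self) -> np.ndarray:
        return np.maximum(self.h, 0.0)

    @classmethod
    def zeros(cls) -> "CircuitState":
        return cls(h=np.zeros(N_UNITS))


@dataclass(frozen=True)
class PerturbationSpec:
    """Extra excitatory input into one or more interneuron classes.

    ``targets`` maps interneuron class ("PV", "SOM", "VIP") to the injected
    input; "PV" targets both PV units.  ``scope`` selects which level of the
    hierarchy is modulated; ``onset_trial`` the first perturbed trial.
    """

    targets: dict[str, float]
    scope: str = "both"            # "lower" | "higher" | "both"
    onset_trial: int = 0

    def __post_init__(self) -> None:
        for name, mag in self.targets.items():
            if name not in ("PV", "SOM", "VIP"):
                raise ValueError(f"unknown perturbation target {name!r}")
            if mag < 0:
                raise ValueError("perturbation magnitudes must be >= 0 "
                                 "(excitatory modulation only)")
        if self.scope not in ("lower", "higher", "both"):
            raise ValueError(f"unknown scope {self.scope!r}")

    def to_vector(self) -> np.ndarray:
        v = np.zeros(N_UNITS)
        for name, mag in self.targets.items():
            if name == "PV":
                v[UNITS.index("PV1")] += mag
                v[UNITS.index("PV2")] += mag
            else:
                v[UNITS.index(name)] += mag
        return v


@dataclass(frozen=True)
class LinearFit:
    """Least-squares line through a PE neuron's steady-state response curve."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("fit must be finite")


# ---------------------------------------------------------------------------
# Construction: solving the balance constraints
# ---------------------------------------------------------------------------

def _interneuron_slopes(w_fb_I: np.ndarray) -> np.ndarray:
    """Steady-state response slopes of the interneuron subsystem.

    With the PE somata silent, the four interneurons form an autonomous
    linear subsystem.  Returns a (4, 2) array of (d r_i / d s, d r_i / d p)
    for i in (PV1, PV2, SOM, VIP), where s is the stimulus and p the
    prediction.
    """
    W_ii = np.zeros((4, 4))
    W_ii[0, 2] = W_ii[0, 3] = -_W_I_TO_PV    # SOM, VIP -> PV1
    W_ii[1, 2] = W_ii[1, 3] = -_W_I_TO_PV    # SOM, VIP -> PV2
    W_ii[2, 3] = -_W_SOM_VIP                 # VIP -> SOM
    W_ii[3, 2] = -_W_SOM_VIP                 # SOM -> VIP
    drive = np.zeros((4, 2))
    drive[0, 0] = 1.0                        # PV1 <- stimulus
    drive[1, 1] = 1.0                        # PV2 <- prediction
    drive[2, int(w_fb_I[2])] = 1.0           # SOM
    drive[3, int(w_fb_I[3])] = 1.0           # VIP
    return np.linalg.solve(np.eye(4) - W_ii, drive)


def build_mfn(variant: str = "MFN1") -> PECircuitParams:
    """Construct and validate one of the three mean-field circuit variants.

    The sign/routing template is fixed; magnitudes follow from three balance
    conditions.  Writing (c_s, c_p) for the steady-state coefficients of a
    unit's input with respect to stimulus s and prediction p:

    1. *Predicted-input balance.*  Each soma receives s directly, its
       dendrite's (rectified) drive, and PV inhibition; the two PV weights
       are solved from the 2x2 system that pins the total somatic
       coefficients to (-gamma, +gamma) for nE and (+gamma, -gamma) for pE,
       so a fully predicted stimulus (s = p) leaves both somata exactly at
       their zero baseline for any input level, and mismatches evoke
       one-sided linear responses.
    2. *Dendritic operating point.*  Each dendrite receives p directly and
       SOM inhibition weaker than the predicted-manifold drive, so dendrites
       are active (above threshold) during stimulation.  This keeps the
       dendro-somatic pathway in its linear range, where the somatic solve
       can cancel it exactly.
    3. *Neuromodulation neutrality.*  Equal extra drive onto SOM and VIP
       must not shift the PE operating points: the somatic disinhibition via
       the SOM/VIP -> PV pathway has to equal the extra dendritic inhibition
       transmitted to the soma.  Under co-activation both SOM and VIP rates
       rise by delta/(1 + w_SOM<->VIP), which fixes the dendro-somatic
       coupling in closed form: w_soma<-dend * w_dend<-SOM = 2 * w_PV<-SOM *
       (sum of that soma's PV weights).  A neuromodulator hitting VIP alone
       then disinhibits both PE neurons (raising their baselines), one
       hitting SOM alone inhibits them, and co-activation cancels.

    Raises :class:`CircuitBuildError` if the solve leaves the sign cone or
    the resulting circuit fails response validation.
    """
    if variant not in _TEMPLATE:
        raise ValueError(f"unknown variant {variant!r}; expected MFN1/MFN2/MFN3")
    tpl = _TEMPLATE[variant]
    w_fb = np.array([1.0 if u in _FB_ROUTING[variant] else 0.0 for u in UNITS])
    w_ff = 1.0 - w_fb

    slopes = _interneuron_slopes(w_fb[_I])
    a_som, b_som = slopes[2]
    if a_som + b_som <= 0:
        raise CircuitBuildError("SOM response does not grow with predicted input")

    # Dendritic input coefficients (d_s, d_p); the predicted-manifold slope
    # d_s + d_p must stay positive so the dendrite is active under
    # stimulation (condition 2).
    dend = {}
    for name, w_d_som in (("nD", tpl["w_nd_som"]), ("pD", tpl["w_pd_som"])):
        d_s = -w_d_som * a_som
        d_p = 1.0 - w_d_som * b_som
        if d_s + d_p <= 0:
            raise CircuitBuildError(f"{name} silent on the predicted manifold")
        dend[name] = (d_s, d_p)

    # Somatic PV weights: [[a_PV1, a_PV2], [b_PV1, b_PV2]] @ w = rhs, where
    # the rhs depends linearly on the dendro-somatic coupling w_dend.  The
    # neutrality condition w_dend * w_d_som = 2 U (w1 + w2) is linear in
    # w_dend as well, so it has a closed-form solution.
    P = slopes[:2].T
    try:
        P_inv = np.linalg.inv(P)
    except np.linalg.LinAlgError as exc:
        raise CircuitBuildError("singular PV slope matrix") from exc

    def solve_soma(gamma: float, sign: float, d_coef: tuple[float, float],
                   w_d_som: float, check_far_field: bool) -> tuple[np.ndarray, float]:
        # sign = -1 for nE (responds to p > s), +1 for pE.
        d_s, d_p = d_coef
        # w(w_dend) = P_inv @ (rhs0 + w_dend * rhs1)
        rhs0 = np.array([1.0 - sign * gamma, sign * gamma])
        rhs1 = np.array([d_s, d_p])
        w0 = P_inv @ rhs0
        w1 = P_inv @ rhs1
        s0, s1 = w0.sum(), w1.sum()
        denom = w_d_som - 2.0 * _W_I_TO_PV * s1
        if abs(denom) < 1e-12:
            raise CircuitBuildError("degenerate neutrality condition")
        w_dend = 2.0 * _W_I_TO_PV * s0 / denom
        if w_dend < 0:
            raise CircuitBuildError("negative dendro-somatic coupling")
        w_pv = w0 + w_dend * w1
        if np.any(w_pv < -1e-9):
            raise CircuitBuildError(
                f"balance solve left the non-negative weight cone: {w_pv}")
        if check_far_field and -gamma - w_dend * d_s > -0.05:
            # Once the dendrite rectifies (large under-predicted inputs) the
            # soma loses the dendritic part of its stimulus cancellation;
            # gamma must be large enough that nE stays below threshold there.
            raise CircuitBuildError(
                "gamma_n too small: nPE would respond to under-predicted "
                "inputs beyond the dendritic range")
        return np.clip(w_pv, 0, None), w_dend

    w_ne, w_soma_nd = solve_soma(tpl["gamma_n"], -1.0, dend["nD"],
                                 tpl["w_nd_som"], True)
    w_pe, w_soma_pd = solve_soma(tpl["gamma_p"], +1.0, dend["pD"],
                                 tpl["w_pd_som"], False)

    W = np.zeros((N_UNITS, N_UNITS))
    W[0, 2] = w_soma_nd                 # nD -> nE
    W[1, 3] = w_soma_pd                 # pD -> pE
    W[0, 4:6] = -w_ne                   # PV -> nE
    W[1, 4:6] = -w_pe                   # PV -> pE
    W[2, 6] = -tpl["w_nd_som"]          # SOM -> nD
    W[3, 6] = -tpl["w_pd_som"]          # SOM -> pD
    W[4:6, 6] = -_W_I_TO_PV             # SOM -> PV
    W[4:6, 7] = -_W_I_TO_PV             # VIP -> PV
    W[6, 7] = -_W_SOM_VIP               # VIP -> SOM
    W[7, 6] = -_W_SOM_VIP               # SOM -> VIP

    params = PECircuitParams(W=W, w_ff=w_ff, w_fb=w_fb,
                             I_bg=np.zeros(N_UNITS), variant=variant)
    params.I_bg = calibrate_background(params)
    report = verify_pe_responses(params)
    if not report.passed:
        raise CircuitBuildError(
            "constructed circuit failed response validation: "
            + "; ".join(report.failures))
    return params


def calibrate_background(
    params: PECircuitParams,
    target_baselines: np.ndarray | None = None,
    check: bool = True,
    tol: float = 0.01,
) -> np.ndarray:
    """Background inputs that hold the circuit at the target baseline rates.

    At the baseline fixed point the excitatory compartments sit exactly at
    threshold (h = r = 0) and the interneurons are active (h = r = target),
    so the steady-state condition h* = W r* + I_bg is solved directly as
    ``I_bg = h* - W r*``.  When ``check`` is set, the calibrated circuit is
    simulated with zero stimulus and zero prediction and the residual must be
    below ``tol`` (default 0.01 /s); otherwise the prescribed rectification
    pattern admits no steady state and a :class:`CircuitBuildError` is raised.
    """
    r_t = DEFAULT_BASELINES if target_baselines is None else np.asarray(
        target_baselines, float)
    I_bg = r_t - params.W @ r_t
    if check:
        test = replace_bg(params, I_bg)
        r = simulate_circuit(test, ff=0.0, fb=0.0, duration_ms=2000.0)
        if np.max(np.abs(r - r_t)) > tol:
            raise CircuitBuildError(
                f"calibration residual {np.max(np.abs(r - r_t)):.3g} exceeds {tol}")
    return I_bg


def replace_bg(params: PECircuitParams, I_bg: np.ndarray) -> PECircuitParams:
    """Copy of ``params`` with a different background input."""
    return PECircuitParams(W=params.W.copy(), w_ff=params.w_ff.copy(),
                           w_fb=params.w_fb.copy(), I_bg=np.asarray(I_bg, float),
                           tau=params.tau.copy(), variant=params.variant)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def _rhs(h: np.ndarray, params: PECircuitParams, ff: float, fb: float,
         pert: np.ndarray | None) -> np.ndarray:
    r = np.maximum(h, 0.0)
    inp = params.W @ r + params.w_ff * ff + params.w_fb * fb + params.I_bg
    if pert is not None:
        inp = inp + pert
    return (-h + inp) / params.tau


def step_circuit(
    state: CircuitState,
    params: PECircuitParams,
    ff: float,
    fb: float,
    pert: PerturbationSpec | np.ndarray | None = None,
    dt: float = 1.0,
) -> CircuitState:
    """One second-order Runge-Kutta (Heun) step of the circuit ODEs.

    Rectification is applied when forming rates at both stage evaluations.
    Raises on non-positive ``dt`` or non-finite state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    pvec = pert.to_vector() if isinstance(pert, PerturbationSpec) else pert
    k1 = _rhs(state.h, params, ff, fb, pvec)
    k2 = _rhs(state.h + dt * k1, params, ff, fb, pvec)
    h = state.h + 0.5 * dt * (k1 + k2)
    if not np.all(np.isfinite(h)):
        raise FloatingPointError("circuit state diverged (NaN/Inf)")
    return CircuitState(h=h)


def simulate_circuit(
    params: PECircuitParams,
    ff: float | np.ndarray,
    fb: float | np.ndarray,
    pert: PerturbationSpec | np.ndarray | None = None,
    duration_ms: float | None = None,
    dt: float = 1.0,
    state: CircuitState | None = None,
    record: bool = False,
) -> np.ndarray:
    """Integrate the circuit under scalar or per-step inputs.

    Returns the final rate vector, or the full ``(n, 8)`` rate trajectory when
    ``record`` is set.  Scalar inputs require ``duration_ms``.
    """
    if np.isscalar(ff) and np.isscalar(fb):
        if duration_ms is None:
            raise ValueError("duration_ms required for scalar inputs")
        n = int(round(duration_ms / dt))
        ff_arr = np.full(n, float(ff))
        fb_arr = np.full(n, float(fb))
    else:
        ff_arr = np.asarray(ff, float)
        fb_arr = np.broadcast_to(np.asarray(fb, float), ff_arr.shape)
        n = ff_arr.size
    st = CircuitState.zeros() if state is None else state
    out = np.empty((n, N_UNITS)) if record else None
    for i in range(n):
        st = step_circuit(st, params, ff_arr[i], fb_arr[i], pert, dt)
        if record:
            out[i] = st.r
    return out if record else st.r


# ---------------------------------------------------------------------------
# Validation and characterization
# ---------------------------------------------------------------------------

@dataclass
class PEValidationReport:
    """Outcome of the PE-response validation probe."""

    passed: bool
    baseline: np.ndarray
    responses: dict[float, tuple[float, float]]   # mismatch -> (r_nE, r_pE)
    gain_npe: float
    gain_ppe: float
    failures: list[str]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"PE response validation: {'PASS' if self.passed else 'FAIL'}",
                 f"  baseline rates: {np.round(self.baseline, 4)}",
                 f"  gains: nPE={self.gain_npe:.4f}, pPE={self.gain_ppe:.4f}"]
        for mm, (rn, rp) in sorted(self.responses.items()):
            lines.append(f"  mismatch {mm:+.2f}: nE={rn:.4f}  pE={rp:.4f}")
        lines += [f"  FAIL: {f}" for f in self.failures]
        return "\n".join(lines)


SILENT_TOL = 1e-3   # a PE rate below this counts as baseline-silent


def verify_pe_responses(
    params: PECircuitParams,
    prediction: float = 5.0,
    mismatches: Sequence[float] = (-3.0, -1.5, 0.0, 1.5, 3.0),
    settle_ms: float = 3000.0,
) -> PEValidationReport:
    """Probe steady-state PE responses against the defining pattern.

    For stimulus = prediction both PE somata must stay at baseline; for
    stimulus above (below) the prediction only the pPE (nPE) soma may respond.
    Also verifies the baseline fixed point and measures the response gains.
    """
    failures: list[str] = []
    baseline = simulate_circuit(params, 0.0, 0.0, duration_ms=settle_ms)
    if np.max(np.abs(baseline - DEFAULT_BASELINES)) > 0.01:
        failures.append(f"baseline rates off target: {np.round(baseline, 3)}")

    responses: dict[float, tuple[float, float]] = {}
    for mm in mismatches:
        r = simulate_circuit(params, prediction + mm, prediction,
                             duration_ms=settle_ms)
        rn, rp = r[0], r[1]
        responses[mm] = (rn, rp)
        if mm == 0 and (rn > SILENT_TOL or rp > SILENT_TOL):
            failures.append(f"PE response to fully predicted input: {rn:.4g}, {rp:.4g}")
        if mm > 0 and (rp <= SILENT_TOL or rn > SILENT_TOL):
            failures.append(f"mismatch {mm:+}: expected pPE-only response")
        if mm < 0 and (rn <= SILENT_TOL or rp > SILENT_TOL):
            failures.append(f"mismatch {mm:+}: expected nPE-only response")

    neg = sorted(m for m in mismatches if m < 0)
    pos = sorted(m for m in mismatches if m > 0)
    gain_n = ((responses[neg[0]][0] - responses[neg[-1]][0])
              / (neg[-1] - neg[0])) if len(neg) >= 2 else float("nan")
    gain_p = ((responses[pos[-1]][1] - responses[pos[0]][1])
              / (pos[-1] - pos[0])) if len(pos) >= 2 else float("nan")
    if not (gain_n > 0 and gain_p > 0):
        failures.append(f"non-positive gains: nPE={gain_n}, pPE={gain_p}")
    return PEValidationReport(passed=not failures, baseline=baseline,
                              responses=responses, gain_npe=gain_n,
                              gain_ppe=gain_p, failures=failures)


def measure_gains(params: PECircuitParams, prediction: float = 5.0) -> tuple[float, float]:
    """Steady-state response gains (g_nPE, g_pPE) from two-point probes."""
    rep = verify_pe_responses(params, prediction=prediction)
    if not rep.passed:
        raise CircuitBuildError("cannot measure gains of an invalid circuit: "
                                + "; ".join(rep.failures))
    return rep.gain_npe, rep.gain_ppe


def fit_baseline_gain(
    params: PECircuitParams,
    pert: PerturbationSpec | np.ndarray | None = None,
    input_range: tuple[float, float] = (0.0, 2.5),
    n_probe: int = 6,
    prediction: float = 5.0,
    settle_ms: float = 3000.0,
) -> dict[str, LinearFit]:
    """Fit a line to each PE neuron's steady-state activity over a mismatch range.

    The nPE neuron is probed with negative mismatches (stimulus below the
    prediction), the pPE neuron with positive ones; both fits are against the
    mismatch magnitude, so the intercept is the extrapolated baseline and the
    slope the response gain.  An excitatory interneuron perturbation shifts
    both (e.g. PV activation lowers baseline and gain).
    """
    mags = np.linspace(input_range[0], input_range[1], n_probe)
    r_n = np.empty(n_probe)
    r_p = np.empty(n_probe)
    for i, m in enumerate(mags):
        rn = simulate_circuit(params, prediction - m, prediction, pert,
                              duration_ms=settle_ms)
        rp = simulate_circuit(params, prediction + m, prediction, pert,
                              duration_ms=settle_ms)
        if not (np.all(np.isfinite(rn)) and np.all(np.isfinite(rp))):
            raise FloatingPointError("probe simulation diverged")
        r_n[i], r_p[i] = rn[0], rp[1]
    cn = np.polyfit(mags, r_n, 1)
    cp = np.polyfit(mags, r_p, 1)
    return {"nPE": LinearFit(slope=float(cn[0]), intercept=float(cn[1])),
            "pPE": LinearFit(slope=float(cp[0]), intercept=float(cp[1]))}
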