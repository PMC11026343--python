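"""Delayed, stochastic Jansen-Rit brain-network dynamics.

Each region is a Jansen-Rit neural mass: three subpopulations (pyramidal
cells, excitatory and inhibitory interneurons) whose mean postsynaptic
potentials ``y0, y1, y2`` (and derivatives ``y3, y4, y5``) evolve as coupled
second-order ODEs.  Regions communicate through firing rates delayed by
axonal conduction (``d_ji = L_ji / s``) and scaled by a global coupling
factor ``g`` acting on the normalized structural weights.  Each region also
receives an intrinsic noisy drive ``eta ~ N(p, sigma)`` (an input firing
rate, sampled once per integration step).

Units: voltages mV, time ms, rates ms^-1, conduction speed m/s (= mm/ms).

Integration is stochastic Heun.  Because the Jansen-Rit node is bistable at
the default drive (an alpha limit cycle coexists with a low-activity fixed
point), states are initialized on the depolarized equilibrium branch, inside
the basin of the alpha cycle; see :func:`equilibrium_state`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .connectome import Connectome

__all__ = [
    "JRGlobalParams",
    "JRRegionalParams",
    "NeuralRecording",
    "sigmoid",
    "delays_from_lengths",
    "network_input",
    "jr_derivatives",
    "equilibrium_state",
    "integrate_network",
    "regional_firing_rate",
]

_BLOWUP_MV = 1.0e6


@dataclass
class JRGlobalParams:
    """Region-independent Jansen-Rit and network parameters (defaults are
    the standard simulation values)."""

    Hi: float = 22.0        # mV, inhibitory synaptic gain
    tau_e: float = 10.0     # ms, excitatory PSP time constant
    tau_i: float = 20.0     # ms, inhibitory PSP time constant
    Cpe: float = 135.0      # pyramidal -> excitatory interneuron contacts
    Cpi: float = 33.75      # pyramidal -> inhibitory interneuron contacts
    e0: float = 0.0025      # ms^-1, half the maximum firing rate
    r: float = 0.56         # mV^-1, sigmoid slope
    v0: float = 6.0         # mV, half-activation potential
    p: float = 0.1085       # ms^-1, mean of the intrinsic noisy input
    sigma: float = 0.022    # ms^-1, s.d. of the intrinsic noisy input
    g: float = 25.0         # global coupling factor
    s: float = 20.0         # m/s, conduction speed

    def __post_init__(self):
        for name, val in asdict(self).items():
            if name in ("g", "sigma"):  # may be zero (decoupled/noiseless)
                if val < 0:
                    raise ValueError(f"{name} must be non-negative")
            elif not val > 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class JRRegionalParams:
    """The disease-modifiable parameters, one value per region.

    ``He`` (excitatory gain) rises under toxic amyloid; ``Cip`` (inhibitory
    contacts onto pyramidals) falls under both proteins; ``Cep`` (excitatory
    interneuron contacts onto pyramidals) falls under toxic tau.  Scalars
    broadcast to all regions.
    """

    He: np.ndarray | float = 3.25
    Cip: np.ndarray | float = 33.75
    Cep: np.ndarray | float = 108.0

    def broadcast(self, n: int) -> "JRRegionalParams":
        return JRRegionalParams(
            He=np.broadcast_to(np.asarray(self.He, float), n).copy(),
            Cip=np.broadcast_to(np.asarray(self.Cip, float), n).copy(),
            Cep=np.broadcast_to(np.asarray(self.Cep, float), n).copy(),
        )


@dataclass
class NeuralRecording:
    """Retained per-region pyramidal-potential traces ``y1 - y2``.

    ``data`` has shape (n_regions, n_samples) in mV, sampled every
    ``dt_ms`` after discarding the first ``discard_ms`` of the simulation.
    """

    data: np.ndarray
    dt_ms: float
    discard_ms: float
    meta: dict = field(default_factory=dict)

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def fs(self) -> float:
        """Sampling frequency in Hz."""
        return 1000.0 / self.dt_ms

    @property
    def duration_ms(self) -> float:
        return self.data.shape[1] * self.dt_ms

    def save(self, path: str | Path) -> None:
        """Persist as delimited text (time column + one column per region)
        with a JSON metadata sidecar."""
        path = Path(path)
        t = np.arange(self.data.shape[1]) * self.dt_ms
        np.savetxt(path, np.column_stack([t, self.data.T]))
        sidecar = dict(dt_ms=self.dt_ms, discard_ms=self.discard_ms,
                       **self.meta)
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "NeuralRecording":
        path = Path(path)
        arr = np.loadtxt(path, ndmin=2)
        meta = json.loads(
            path.with_suffix(path.suffix + ".json").read_text())
        return cls(data=arr[:, 1:].T, dt_ms=meta.pop("dt_ms"),
                   discard_ms=meta.pop("discard_ms"), meta=meta)


def sigmoid(v, e0: float = 0.0025, r: float = 0.56, v0: float = 6.0):
    """Voltage-to-rate transfer ``S(v) = 2 e0 / (1 + exp(r (v0 - v)))``.

    Strictly increasing, with ``S(v0) = e0`` and range (0, 2 e0).
    """
    x = np.clip(r * (v0 - np.asarray(v, float)), -700.0, 700.0)
    return 2.0 * e0 / (1.0 + np.exp(x))


def delays_from_lengths(lengths_mm: np.ndarray, s: float, dt_ms: float
                        ) -> np.ndarray:
    """Integer-step conduction delays ``round(L / (s dt))``.

    ``s`` in m/s equals mm/ms, so ``L/s`` is already in ms.  Self-delays
    are zero.
    """
    if s <= 0 or dt_ms <= 0:
        raise ValueError("s and dt_ms must be positive")
    ell = np.asarray(lengths_mm, float)
    if np.any(ell < 0):
        raise ValueError("negative lengths")
    d = np.floor(ell / (s * dt_ms) + 0.5).astype(np.intp)
    if d.ndim == 2:
        np.fill_diagonal(d, 0)
    return d


def network_input(i, t, history: np.ndarray, weights: np.ndarray,
                  delays: np.ndarray, g: float, noise_sample,
                  e0: float = 0.0025, r: float = 0.56, v0: float = 6.0):
    """Total input ``I_i(t) = eta_i + g sum_j w_ji S[v_j(t - d_ji)]``.

    ``history`` holds past pyramidal potentials ``v = y1 - y2`` as an array
    of shape (T, n) where row ``t`` is time step ``t``; reads before step 0
    return the initial row.  ``delays`` are integer steps.
    """
    history = np.atleast_2d(np.asarray(history, float))
    n = history.shape[1]
    d = np.asarray(delays)
    lag = t - d[:, i]
    if np.any(t - d[:, i] >= history.shape[0]):
        raise IndexError("requested time beyond stored history")
    lag = np.clip(lag, 0, None)
    v_del = history[lag, np.arange(n)]
    return noise_sample + g * float(
        weights[:, i] @ sigmoid(v_del, e0, r, v0))


def jr_derivatives(y: np.ndarray, inputs: np.ndarray,
                   glob: JRGlobalParams, reg: JRRegionalParams) -> np.ndarray:
    """Right-hand side of the six Jansen-Rit ODEs for all regions.

    ``y`` has shape (6, n); ``inputs`` is the per-region total input
    ``I_i(t)`` in ms^-1.  Returns d``y``/dt with the same shape.
    """
    y = np.atleast_2d(np.asarray(y, float).reshape(6, -1))
    n = y.shape[1]
    reg = reg.broadcast(n)
    e0, r, v0 = glob.e0, glob.r, glob.v0
    te, ti = glob.tau_e, glob.tau_i
    dy = np.empty_like(y)
    dy[0] = y[3]
    dy[1] = y[4]
    dy[2] = y[5]
    dy[3] = (reg.He / te) * sigmoid(y[1] - y[2], e0, r, v0) \
        - (2.0 / te) * y[3] - y[0] / te**2
    dy[4] = (reg.He / te) * (inputs + reg.Cep * sigmoid(glob.Cpe * y[0],
                                                        e0, r, v0)) \
        - (2.0 / te) * y[4] - y[1] / te**2
    dy[5] = (glob.Hi / ti) * reg.Cip * sigmoid(glob.Cpi * y[0], e0, r, v0) \
        - (2.0 / ti) * y[5] - y[2] / ti**2
    return dy


def _fp_residual(v: float, I: float, glob: JRGlobalParams,
                 He: float, Cip: float, Cep: float) -> float:
    """Residual of the scalar fixed-point condition in v = y1 - y2."""
    y0 = He * glob.tau_e * sigmoid(v, glob.e0, glob.r, glob.v0)
    y1 = He * glob.tau_e * (
        I + Cep * sigmoid(glob.Cpe * y0, glob.e0, glob.r, glob.v0))
    y2 = glob.Hi * glob.tau_i * Cip * sigmoid(
        glob.Cpi * y0, glob.e0, glob.r, glob.v0)
    return y1 - y2 - v


def equilibrium_state(inputs, glob: JRGlobalParams, reg: JRRegionalParams,
                      branch: str = "upper", n: int | None = None
                      ) -> np.ndarray:
    """Noiseless equilibrium of decoupled nodes under constant input.

    For drives below the oscillation onset the node has up to three fixed
    points; ``branch='upper'`` selects the depolarized one, which sits
    inside the basin of attraction of the alpha limit cycle, and
    ``branch='lower'`` the hyperpolarized one.  Returns a (6, n) state with
    zero derivatives.
    """
    inputs = np.atleast_1d(np.asarray(inputs, float))
    if n is None:
        n = inputs.size
    inputs = np.broadcast_to(inputs, n)
    reg = reg.broadcast(n)
    y = np.zeros((6, n))
    vs = np.linspace(-40.0, 60.0, 2001)
    for i in range(n):
        args = (inputs[i], glob, float(reg.He[i]), float(reg.Cip[i]),
                float(reg.Cep[i]))
        res = _fp_residual(vs, *args)
        sign_change = (res[:-1] == 0) | (res[:-1] * res[1:] < 0)
        roots = [brentq(_fp_residual, vs[k], vs[k + 1], args=args)
                 for k in np.flatnonzero(sign_change)]
        if not roots:
            raise RuntimeError("no fixed point found")
        v = max(roots) if branch == "upper" else min(roots)
        y0 = reg.He[i] * glob.tau_e * sigmoid(v, glob.e0, glob.r, glob.v0)
        y1 = reg.He[i] * glob.tau_e * (
            inputs[i] + reg.Cep[i] * sigmoid(glob.Cpe * y0, glob.e0,
                                             glob.r, glob.v0))
        y2 = glob.Hi * glob.tau_i * reg.Cip[i] * sigmoid(
            glob.Cpi * y0, glob.e0, glob.r, glob.v0)
        y[:3, i] = (y0, y1, y2)
    return y


def integrate_network(
    connectome: Connectome | None,
    glob: JRGlobalParams | None = None,
    regional: JRRegionalParams | None = None,
    duration_ms: float = 10_000.0,
    discard_ms: float = 2_000.0,
    dt_ms: float = 1.0,
    rng_seed: int | np.random.SeedSequence = 0,
    weights: np.ndarray | None = None,
) -> NeuralRecording:
    """Simulate the delayed stochastic Jansen-Rit network.

    Parameters
    ----------
    connectome : Connectome or None
        ``None`` runs a single decoupled node (the intrinsic noise mean
        ``p`` then stands in for the missing interregional afferences).
    weights : ndarray, optional
        Override the connectome's weights (used by the closed loop, where
        weights decay with tau damage while lengths stay fixed).
    rng_seed : int or numpy SeedSequence
        Noise is deterministic given the seed.

    Returns
    -------
    NeuralRecording
        The retained ``y1 - y2`` traces sampled at every step after
        ``discard_ms``.

    Raises
    ------
    RuntimeError
        On numerical blow-up (any ``|y| > 1e6`` mV).
    """
    glob = glob or JRGlobalParams()
    regional = regional or JRRegionalParams()
    if duration_ms <= discard_ms:
        raise ValueError("duration must exceed the discarded transient")

    if connectome is None:
        n = 1
        w = np.zeros((1, 1))
        d = np.zeros((1, 1), dtype=np.intp)
    else:
        n = connectome.n
        w = np.asarray(weights if weights is not None
                       else connectome.weights, float)
        d = delays_from_lengths(connectome.lengths, glob.s, dt_ms)
    reg = regional.broadcast(n)
    rng = np.random.default_rng(rng_seed)

    n_steps = int(round(duration_ms / dt_ms))
    keep_from = int(round(discard_ms / dt_ms))
    horizon = int(d.max()) + 2

    y = equilibrium_state(glob.p, glob, reg, branch="upper", n=n)
    buf = np.empty((horizon, n))
    buf[:] = y[1] - y[2]

    cols = np.broadcast_to(np.arange(n), (n, n))  # j index for gather
    use_coupling = n > 1 and glob.g != 0
    out = np.empty((n, n_steps - keep_from))
    dt = dt_ms
    e0, r, v0 = glob.e0, glob.r, glob.v0
    te, ti, Hi = glob.tau_e, glob.tau_i, glob.Hi
    He, Cip, Cep = reg.He, reg.Cip, reg.Cep
    Cpe, Cpi, g = glob.Cpe, glob.Cpi, glob.g
    two_e0 = 2.0 * e0

    def S(v):
        return two_e0 / (1.0 + np.exp(np.clip(r * (v0 - v), -700., 700.)))

    def coupled_input(step_idx, eta):
        if not use_coupling:
            return eta
        v_del = buf[(step_idx - d) % horizon, cols]
        return eta + g * (w * S(v_del)).sum(axis=0)

    def deriv(yy, I):
        dy = np.empty_like(yy)
        dy[0] = yy[3]
        dy[1] = yy[4]
        dy[2] = yy[5]
        dy[3] = (He / te) * S(yy[1] - yy[2]) - (2. / te) * yy[3] \
            - yy[0] / te**2
        dy[4] = (He / te) * (I + Cep * S(Cpe * yy[0])) - (2. / te) * yy[4] \
            - yy[1] / te**2
        dy[5] = (Hi / ti) * Cip * S(Cpi * yy[0]) - (2. / ti) * yy[5] \
            - yy[2] / ti**2
        return dy

    check_every = max(1, int(100 / dt_ms))
    for t in range(n_steps):
        eta = glob.p + glob.sigma * rng.standard_normal(n)
        f1 = deriv(y, coupled_input(t, eta))
        yp = y + dt * f1
        # stage 2 sees the predictor value at t+1 for zero-delay reads
        buf[(t + 1) % horizon] = yp[1] - yp[2]
        f2 = deriv(yp, coupled_input(t + 1, eta))
        y = y + (dt / 2.0) * (f1 + f2)
        v = y[1] - y[2]
        buf[(t + 1) % horizon] = v
        if t % check_every == 0 and (
                not np.all(np.isfinite(y)) or np.abs(y).max() > _BLOWUP_MV):
            raise RuntimeError(
                f"neural integration blow-up at t={t * dt_ms:.0f} ms "
                f"(max |y| = {np.abs(y[np.isfinite(y)]).max():.3g} mV)")
        if t >= keep_from:
            out[:, t - keep_from] = v
    if not np.all(np.isfinite(y)):
        raise RuntimeError("neural integration produced non-finite state")

    return NeuralRecording(
        data=out, dt_ms=dt_ms, discard_ms=discard_ms,
        meta=dict(n_regions=n, duration_ms=duration_ms,
                  g=glob.g, s=glob.s, p=glob.p, sigma=glob.sigma))


def regional_firing_rate(recording: NeuralRecording,
                         e0: float = 0.0025, r: float = 0.56,
                         v0: float = 6.0) -> np.ndarray:
    """Mean pyramidal firing rate per region, ms^-1.

    The time-average of ``S[y1 - y2]`` over the retained window; always in
    (0, 2 e0).
    """
    if recording.data.size == 0:
        raise ValueError("empty recording window")
    return sigmoid(recording.data, e0, r, v0).mean(axis=1)
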