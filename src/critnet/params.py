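"""Parameter containers for the binary E/I network model.

The model is a recurrent network of ``N`` probabilistic binary neurons.
A fraction ``alpha`` of the neurons is inhibitory.  Each directed pair of
neurons is connected with probability ``p``; excitatory outgoing weights
are uniform on ``[0, w]`` and inhibitory outgoing weights uniform on
``[-g*w, 0]``, so ``g`` is the I/E weight ratio.  Every neuron also fires
spontaneously with probability ``p_ext`` per time step (default
``0.005/N``, i.e. one externally driven spike per 200 steps across the
whole network).
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the network and its external drive.

    Attributes
    ----------
    N : int
        Number of neurons.
    p : float
        Connection probability for each directed neuron pair.
    alpha : float
        Fraction of inhibitory neurons; ``alpha * N`` must be an integer.
    w : float
        Excitatory weight scale (maximum uniform excitatory weight).
    g : float
        I/E weight ratio; inhibitory weights are drawn in ``[-g*w, 0]``.
    p_ext : float or None
        Per-neuron external firing probability per step.  ``None`` resolves
        to ``0.005 / N``.
    seed : int or None
        Seed for the quenched connectivity draw (one matrix per seed).
    """

    N: int = 1000
    p: float = 0.2
    alpha: float = 0.2
    w: float = 0.0125
    g: float = 0.0
    p_ext: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p must be in (0, 1], got {self.p}")
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.w <= 0.0:
            raise ValueError(f"w must be positive, got {self.w}")
        if self.g < 0.0:
            raise ValueError(f"g must be non-negative, got {self.g}")
        n_inh = self.alpha * self.N
        if abs(n_inh - round(n_inh)) > 1e-9:
            raise ValueError(
                f"alpha * N must be an integer neuron count, got {n_inh}"
            )
        if self.p_ext is None:
            object.__setattr__(self, "p_ext", 0.005 / self.N)
        if not 0.0 <= self.p_ext <= 1.0:
            raise ValueError(f"p_ext must be in [0, 1], got {self.p_ext}")

    @property
    def n_inhibitory(self) -> int:
        """Number of inhibitory neurons, ``floor(alpha * N)``."""
        return int(round(self.alpha * self.N))

    @property
    def n_excitatory(self) -> int:
        return self.N - self.n_inhibitory

    def with_(self, **kwargs) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimulationConfig:
    """Run-length and initial-condition settings for a simulation.

    ``T_steps`` counts every recorded raster column including the burn-in
    prefix; analysis routines discard the first ``burn_in`` columns.
    ``initial_active`` may be an integer neuron count or a fraction in
    ``(0, 1)``.
    """

    T_steps: int = 500_000
    burn_in: int = 10_000
    initial_active: float = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in < 0:
            raise ValueError(f"burn_in must be >= 0, got {self.burn_in}")
        if self.T_steps <= self.burn_in:
            raise ValueError(
                f"T_steps ({self.T_steps}) must exceed burn_in ({self.burn_in})"
            )
        if self.initial_active < 0:
            raise ValueError("initial_active must be non-negative")

    def n_initial(self, N: int) -> int:
        """Resolve ``initial_active`` to a neuron count for network size N."""
        k = self.initial_active
        if 0 < k < 1:
            k = round(k * N)
        k = int(k)
        if k > N:
            raise ValueError(f"initial_active {k} exceeds N={N}")
        return k
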