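"""Model parameter containers and published default values.

Units are mV, ms, nS, pF and pA throughout.  With these units pF/nS = ms,
so the membrane equation tau_m dV/dt = (V_0 - V) + I/g_0 is dimensionally
closed without conversion factors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "NeuronClassParams",
    "SynapseClassParams",
    "PlasticityParams",
    "EXCITATORY",
    "INHIBITORY",
    "SYNAPSE_CLASSES",
    "DT_MS",
]

#: published forward-Euler step size (ms)
DT_MS = 0.02


@dataclass(frozen=True)
class NeuronClassParams:
    """Conductance-based LIF cell parameters for one neuron class.

    The membrane time constant is derived, tau_m = C_m / g_0.  A stored
    (printed) value may be supplied for cross-checking; it must agree with
    the derived one to within 1%.
    """

    c_m_pf: float
    g0_ns: float
    v_rest_mv: float
    v_thresh_mv: float
    v_reset_mv: float
    tau_refrac_ms: float
    label: str  # "excitatory" | "inhibitory"
    printed_tau_m_ms: float | None = None

    def __post_init__(self) -> None:
        if self.c_m_pf <= 0 or self.g0_ns <= 0:
            raise ValueError("capacitance and leak conductance must be positive")
        if not self.v_thresh_mv > self.v_rest_mv:
            raise ValueError("firing threshold must exceed the resting potential")
        if self.v_reset_mv > self.v_thresh_mv:
            raise ValueError("after-spike potential must not exceed threshold")
        if self.tau_refrac_ms <= 0:
            raise ValueError("refractory period must be positive")
        if self.printed_tau_m_ms is not None:
            derived = self.tau_m_ms
            if abs(derived - self.printed_tau_m_ms) > 0.01 * self.printed_tau_m_ms:
                raise ValueError(
                    f"stored tau_m {self.printed_tau_m_ms} ms deviates more than 1% "
                    f"from C_m/g_0 = {derived:.3f} ms"
                )

    @property
    def tau_m_ms(self) -> float:
        """Membrane time constant C_m/g_0 (pF/nS = ms)."""
        return self.c_m_pf / self.g0_ns


@dataclass(frozen=True)
class SynapseClassParams:
    """Parameters shared by one synapse class (e.g. E->E feedforward).

    ``g_scale_ns`` is the biological scaling constant lambda: an arrival
    increments the synaptic conductance by lambda * dg where dg in [0, 1]
    is the plastic weight, so lambda bounds the product lambda*dg.
    """

    tau_g_ms: float
    reversal_mv: float
    g_scale_ns: float
    plastic: bool

    def __post_init__(self) -> None:
        if self.tau_g_ms <= 0:
            raise ValueError("conductance time constant must be positive")
        if self.g_scale_ns < 0:
            raise ValueError("conductance scaling bound must be non-negative")


@dataclass(frozen=True)
class PlasticityParams:
    """Trace-STDP parameters.

    alpha_c / alpha_d are the saturating trace increments, tau_c / tau_d the
    trace decay time constants, rho the learning rate of the event-driven
    multiplicative weight rule.  ``continuous_tau_dg_ms`` switches to a
    continuous-time weight relaxation with that time constant instead of the
    event-driven rule (both readings of the published rule are supported;
    event-driven is the default).
    """

    alpha_c: float = 0.5
    alpha_d: float = 0.5
    tau_c_ms: float = 25.0
    tau_d_ms: float = 25.0
    rho: float = 0.1
    continuous_tau_dg_ms: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha_c <= 1.0 and 0.0 <= self.alpha_d <= 1.0):
            raise ValueError("trace increments must lie in [0, 1]")
        if self.tau_c_ms <= 0 or self.tau_d_ms <= 0:
            raise ValueError("trace time constants must be positive")
        if self.rho <= 0:
            raise ValueError("learning rate must be positive")


# Published cellular parameters (cortical regular-spiking and fast-spiking
# cells): excitatory tau_m = 500/25 = 20 ms; inhibitory 214/18 = 11.89 ms,
# which the source prints as 12 ms (~1% rounding) -- we derive from C_m/g_0.
EXCITATORY = NeuronClassParams(
    c_m_pf=500.0, g0_ns=25.0, v_rest_mv=-74.0, v_thresh_mv=-53.0,
    v_reset_mv=-57.0, tau_refrac_ms=2.0, label="excitatory",
    printed_tau_m_ms=20.0,
)
INHIBITORY = NeuronClassParams(
    c_m_pf=214.0, g0_ns=18.0, v_rest_mv=-82.0, v_thresh_mv=-53.0,
    v_reset_mv=-58.0, tau_refrac_ms=2.0, label="inhibitory",
    printed_tau_m_ms=12.0,
)

#: published synapse classes, keyed by connection-class label:
#: GfE  Gabor-input -> excitatory feedforward
#: EfE  excitatory -> excitatory feedforward
#: EbE  excitatory -> excitatory feedback
#: ElE  excitatory -> excitatory lateral
#: ElI  excitatory -> inhibitory lateral (non-plastic)
#: IlE  inhibitory -> excitatory lateral (non-plastic)
SYNAPSE_CLASSES: dict[str, SynapseClassParams] = {
    "GfE": SynapseClassParams(tau_g_ms=150.0, reversal_mv=0.0, g_scale_ns=0.4, plastic=True),
    "EfE": SynapseClassParams(tau_g_ms=150.0, reversal_mv=0.0, g_scale_ns=1.6, plastic=True),
    "EbE": SynapseClassParams(tau_g_ms=150.0, reversal_mv=0.0, g_scale_ns=1.6, plastic=True),
    "ElE": SynapseClassParams(tau_g_ms=150.0, reversal_mv=0.0, g_scale_ns=1.6, plastic=True),
    "ElI": SynapseClassParams(tau_g_ms=2.0, reversal_mv=0.0, g_scale_ns=40.0, plastic=False),
    "IlE": SynapseClassParams(tau_g_ms=5.0, reversal_mv=-70.0, g_scale_ns=80.0, plastic=False),
}
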