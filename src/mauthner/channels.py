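"""Stock channel catalogue for the oocyte and Mauthner-cell models.

The three zebrafish low-threshold K+ channels (Kv7.4, Kv1.1, Kv1.1+Kvb2)
are single-gate Boltzmann channels whose half-activation voltage and slope
factor were calibrated so that the emulated 200-ms voltage-clamp protocol,
followed by peak-conductance extraction and a Boltzmann fit, reproduces the
measured oocyte values (Kv7.4: -10.1 mV / 15.4; Kv1.1: -35.4 / 7.4;
Kv1.1+Kvb2: -36.6 / 9.4).  Their tau(V) bells are calibrated against the
measured kinetic contrasts: Kv7.4 half-rise times are >= 10x those of
Kv1.1, and Kvb2 coexpression speeds Kv1.1 half-rise by ~2 ms above -40 mV.
Kvb2 is modelled as a distinct channel variant (shifted Boltzmann, faster
tau, larger default oocyte conductance).

The base cell carries Nav / high-threshold K (Kht) / A-type K (KA) / leak
with Rothman-Manis kinetics (see rm_kinetics) and the fixed Mauthner-model
conductances 6000 / 1500 / 300 / 12 nS (120 / 30 / 6 / 0.24 mS/cm^2 on the
40x40 um compartment).  Reversal potentials: E_Na +30 mV, E_K -90 mV,
E_leak -85 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .gating import GateKinetics, TauBell

__all__ = ["ChannelModel", "build_stock_channels", "stock_channel", "STOCK_NAMES"]

E_NA_MV = 30.0
E_K_MV = -90.0
E_LEAK_MV = -85.0

#: Kvb2 acceleration of the Kv1.1 tau bell, expressed as a downward shift of
#: tau(V) chosen so the half-rise contrast through the 200-ms protocol is
#: ~2 ms above -40 mV (2/ln 2 ms of tau ~ 2 ms of half-rise time).
KVB2_TAU_SHIFT_MS = 2.885


@dataclass(frozen=True)
class ChannelModel:
    """One membrane conductance: kinetics tag + optional Boltzmann gate.

    kinetics is one of "boltzmann" (single activation gate `gate`),
    "leak" (ungated), or "rm_nav" / "rm_kht" / "rm_ka" (multi-gate
    Rothman-Manis kinetics with rate multiplier `rate_scale`).
    """

    name: str
    gbar_nS: float
    e_rev_mV: float
    kinetics: str = "boltzmann"
    gate: GateKinetics | None = None
    rate_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.gbar_nS < 0:
            raise ValueError("gbar must be non-negative")
        if self.kinetics == "boltzmann" and self.gate is None:
            raise ValueError("boltzmann channel requires a gate")
        if self.rate_scale <= 0:
            raise ValueError("rate_scale must be positive")

    def with_gbar(self, gbar_nS: float) -> "ChannelModel":
        return replace(self, gbar_nS=gbar_nS)

    def conductance_nS(self, m: float) -> float:
        """Instantaneous g = gbar * m^p for a Boltzmann channel."""
        if self.gate is None:
            return self.gbar_nS
        return self.gbar_nS * m ** self.gate.exponent_p


def _kv74_gate() -> GateKinetics:
    # Kv7.4 activates orders of magnitude more slowly than Kv1.1; its tau
    # is taken as voltage independent (the 200-ms protocol constrains only
    # its overall magnitude).  The gate midpoint/slope are calibrated
    # through the emulated protocol: with a 200-ms step ending short of
    # steady state and ~1% resting activation at the -80 mV holding level,
    # the values below make the fitted G-V Boltzmann exactly the measured
    # (-10.1 mV, 15.4).
    return GateKinetics(
        v_half_mV=-9.6988722109,
        slope_k_mV=14.6047194105,
        tau=TauBell(500.0, 0.0, -50.0, 40.0, 60.0),
        exponent_p=1,
        q10=3.0,
        t_ref_C=20.0,
    )


def _kv11_gate() -> GateKinetics:
    # fast activation/deactivation (~3.4 ms) with a mild slowing near the
    # spike-threshold region; calibrated through the emulated protocol.
    return GateKinetics(
        v_half_mV=-35.4,
        slope_k_mV=7.4,
        tau=TauBell(3.4, 2.0, -50.0, 3.5, 4.0),
        exponent_p=1,
        q10=3.0,
        t_ref_C=20.0,
    )


def _kv11_kvb2_gate() -> GateKinetics:
    # Kvb2 coexpression: tau lowered by ~2/ln2 ms above -40 mV so the
    # half-rise contrast through the step protocol is ~2 ms, with a modest
    # slow deactivation region below -60 mV (unconstrained by the 200-ms
    # step family, which only samples commands of -80 mV and above with
    # appreciable current above -40 mV).
    return GateKinetics(
        v_half_mV=-36.6,
        slope_k_mV=9.4,
        tau=TauBell(3.4 - KVB2_TAU_SHIFT_MS, 2.0, -60.0, 5.0, 8.0),
        exponent_p=1,
        q10=3.0,
        t_ref_C=20.0,
    )


def _catalogue() -> dict[str, ChannelModel]:
    return {
        # low-threshold K+ channels; default gbar is the oocyte-scale value
        # (uS range) used by the voltage-clamp emulation, the M-cell model
        # overrides it with the conductance under study.
        "Kv7.4": ChannelModel("Kv7.4", 20_000.0, E_K_MV, "boltzmann", _kv74_gate()),
        "Kv1.1": ChannelModel("Kv1.1", 30_000.0, E_K_MV, "boltzmann", _kv11_gate()),
        "Kv1.1+Kvb2": ChannelModel(
            "Kv1.1+Kvb2", 60_000.0, E_K_MV, "boltzmann", _kv11_kvb2_gate()
        ),
        # base-cell channel set (Mauthner model defaults)
        "Nav": ChannelModel("Nav", 6000.0, E_NA_MV, "rm_nav"),
        "Kht": ChannelModel("Kht", 1500.0, E_K_MV, "rm_kht"),
        "KA": ChannelModel("KA", 300.0, E_K_MV, "rm_ka"),
        "leak": ChannelModel("leak", 12.0, E_LEAK_MV, "leak"),
    }


STOCK_NAMES = tuple(_catalogue().keys())

_ALIASES = {
    "kv7.4": "Kv7.4",
    "kv74": "Kv7.4",
    "kv1.1": "Kv1.1",
    "kv11": "Kv1.1",
    "kv1.1+kvb2": "Kv1.1+Kvb2",
    "kv11+kvb2": "Kv1.1+Kvb2",
    "kv1.1+kvbeta2": "Kv1.1+Kvb2",
    "nav": "Nav",
    "kht": "Kht",
    "ka": "KA",
    "leak": "leak",
}


def stock_channel(name: str) -> ChannelModel:
    """Return one stock channel by (case-insensitive) name."""
    key = _ALIASES.get(name.lower())
    if key is None:
        raise KeyError(
            f"unknown channel {name!r}; available: {', '.join(STOCK_NAMES)}"
        )
    return _catalogue()[key]


def build_stock_channels(names=None) -> dict[str, ChannelModel]:
    """Build the stock catalogue (all channels, or the requested subset)."""
    if names is None:
        return _catalogue()
    return {n: stock_channel(n) for n in names}
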