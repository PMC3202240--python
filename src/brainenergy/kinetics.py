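"""Pure rate-law evaluators for the six kinetic-law forms.

Every reaction in the compartmental models is assigned exactly one of six
kinetic forms; the same functions serve as the single source of truth for
the ODE assembler and for brute-force oracles in the test suite.

Conventions
-----------
Concentrations are in mM, fluxes/rates in mM min^-1 referenced to the
law's source (host) compartment.  All evaluators are scalar pure
functions; vectorised variants used by the simulator live in
:mod:`brainenergy.simulator` and are regression-tested against these.
"""

from __future__ import annotations

from collections.abc import Sequence

__all__ = [
    "KineticsDomainError",
    "passive_diffusion_flux",
    "facilitated_transport_flux",
    "bimolecular_saturating_rate",
    "michaelis_menten_rate",
    "mass_action_rate",
    "uncompetitive_inhibition_rate",
    "LAW_FORMS",
    "LAW_PARAMS",
]

#: the six declared kinetic-law forms
LAW_FORMS = (
    "passive_diffusion",
    "facilitated_transport",
    "michaelis_menten",
    "bimolecular_mm",
    "mass_action",
    "uncompetitive_inhibition",
)

#: exact parameter names each form requires (used by model validation)
LAW_PARAMS = {
    "passive_diffusion": ("gamma", "sigma"),
    "facilitated_transport": ("v", "km"),
    "michaelis_menten": ("v_max", "km"),
    "bimolecular_mm": ("j_max", "k"),
    "mass_action": ("k",),
    "uncompetitive_inhibition": ("v_max", "km", "ki"),
}


class KineticsDomainError(ValueError):
    """Raised when a rate law is evaluated outside its domain."""


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise KineticsDomainError(f"{name} must be non-negative, got {value!r}")


def passive_diffusion_flux(gamma: float, sigma: float, c_x: float, c_y: float) -> float:
    """Passive membrane diffusion, linear in both concentrations.

    J = gamma * (C_x - sigma * C_y).  A positive flux is directed x -> y;
    the flux vanishes at the partition equilibrium C_x = sigma * C_y.

    Parameters
    ----------
    gamma : membrane transport coefficient, min^-1 (>= 0)
    sigma : dimensionless partition coefficient (> 0)
    c_x, c_y : compartmental concentrations, mM (>= 0)
    """
    _check_nonneg("gamma", gamma)
    if sigma <= 0:
        raise KineticsDomainError(f"sigma must be positive, got {sigma!r}")
    _check_nonneg("c_x", c_x)
    _check_nonneg("c_y", c_y)
    return gamma * (c_x - sigma * c_y)


def facilitated_transport_flux(v: float, km: float, c_x: float) -> float:
    """Carrier-mediated (facilitated) transport, Michaelis-Menten in the
    source-side concentration only.

    J = v * C_x / (km + C_x); monotone increasing in ``c_x`` and bounded
    above by the transport capacity ``v``.
    """
    _check_nonneg("v", v)
    if km <= 0:
        raise KineticsDomainError(f"km must be positive, got {km!r}")
    _check_nonneg("c_x", c_x)
    return v * c_x / (km + c_x)


def michaelis_menten_rate(v_max: float, km: float, s: float) -> float:
    """Irreversible single-substrate Michaelis-Menten rate.

    Same functional form as :func:`facilitated_transport_flux`, enzymatic
    context: v = V_max * S / (K_m + S).
    """
    return facilitated_transport_flux(v_max, km, s)


def bimolecular_saturating_rate(j_max: float, k: float, c_x: float, c_y: float) -> float:
    """Saturating rate law for bimolecular steps X + Y -> Z + W.

    J = J_max * (C_x * C_y) / (K + C_x * C_y) with K in mM^2 (the product
    form; see the methods note for the rationale).  Symmetric in the two
    substrates and bounded by ``j_max``.
    """
    _check_nonneg("j_max", j_max)
    if k <= 0:
        raise KineticsDomainError(f"k must be positive, got {k!r}")
    _check_nonneg("c_x", c_x)
    _check_nonneg("c_y", c_y)
    prod = c_x * c_y
    return j_max * prod / (k + prod)


def mass_action_rate(k: float, concentrations: Sequence[float]) -> float:
    """Mass-action rate k * prod(concentrations); reaction order = len(list).

    Zeroth-order steps must be expressed explicitly elsewhere — an empty
    concentration list is a domain error, not an implicit constant rate.
    """
    _check_nonneg("k", k)
    if len(concentrations) == 0:
        raise KineticsDomainError(
            "mass_action_rate requires at least one concentration; "
            "zeroth-order rates must be expressed explicitly"
        )
    rate = k
    for c in concentrations:
        _check_nonneg("concentration", c)
        rate *= c
    return rate


def uncompetitive_inhibition_rate(
    v_max: float, km: float, s: float, ki: float, i: float
) -> float:
    """Uncompetitive inhibition: v = V_max * S / (K_m + S * (1 + I/K_i)).

    Reduces to plain Michaelis-Menten when the inhibitor is absent, and
    tends to zero at saturating inhibitor.
    """
    _check_nonneg("v_max", v_max)
    if km <= 0:
        raise KineticsDomainError(f"km must be positive, got {km!r}")
    if ki <= 0:
        raise KineticsDomainError(f"ki must be positive, got {ki!r}")
    _check_nonneg("s", s)
    _check_nonneg("i", i)
    return v_max * s / (km + s * (1.0 + i / ki))
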