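"""Oxygen sensing and hypoxia-driven gene expression.

Under normoxia, prolyl hydroxylase (PHase) hydroxylates cytosolic HIF-1a
in an O2-dependent mass-action step, marking it for degradation; under
hypoxia HIF-1a escapes degradation, translocates to the nucleus and
activates transcription of the seven regulated genes (GLUT, MCT, HK,
PFK, GAPDH, PK, LDH).  All regulated genes share the same rate
equations, so under identical parameters their trajectories coincide.

The scheme (per cell; concentrations mM, rates mM/min):

    dHIFc/dt = k_syn*PHase - k_deg*PHase*O2*HIFc - k_tr*HIFc
    dHIFn/dt = k_tr*HIFc*(Vc/Vn) - k_ndec*HIFn
    dMn/dt   = basal + v_tx*HIFn/(k_tx + HIFn) - (k_exp + k_dmn)*Mn
    dMc/dt   = k_exp*Mn*(Vn/Vc) - k_dmc*Mc
    dP/dt    = k_tl*Mc - k_dp*P

Translocation and mRNA export are scaled by the nucleus/cytosol volume
ratio so that amounts, not concentrations, are conserved in transit.
Everything except the transcription saturation is linear, which gives a
closed-form steady state (used for initial conditions, for the
normoxic reference protein level, and as a test oracle).

Metabolic coupling is linear: a regulated reaction's capacity is
``base_vmax * protein / protein_ref`` where ``protein_ref`` is the
steady-state protein level at the reference oxygen concentration
(7 mM), so normoxic capacities equal the base values.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "RegulationParams",
    "GeneRegulationState",
    "RegulationDomainError",
    "hif_derivatives",
    "transcription_rate",
    "protein_derivatives",
    "effective_capacity",
    "steady_state",
]


class RegulationDomainError(ValueError):
    """Raised for out-of-domain regulation inputs (negative state etc.)."""


@dataclass(frozen=True)
class RegulationParams:
    """Rate constants of the oxygen-sensing and expression scheme."""

    k_synthesis: float          # 1/min (times PHase, mM -> mM/min)
    k_degradation: float        # 1/(mM^2 min), PHase*O2*HIF mass action
    k_translocation: float      # 1/min
    k_nuclear_decay: float      # 1/min
    phase_concentration: float  # mM, held constant
    basal_transcription: float  # mM/min
    v_transcription: float      # mM/min, HIF-activated V_max
    k_transcription: float      # mM, half-activation constant
    k_export: float             # 1/min
    k_mrna_decay_nucleus: float   # 1/min
    k_mrna_decay_cytosol: float   # 1/min
    k_translation: float        # 1/min
    k_protein_decay: float      # 1/min

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise RegulationDomainError(f"{name} must be >= 0, got {v}")

    @classmethod
    def from_config(cls, cfg: dict) -> "RegulationParams":
        p = {k: v["value"] for k, v in cfg["params"].items()}
        h = {k: v["value"] for k, v in cfg["hif"].items()}
        return cls(
            k_synthesis=h["k_synthesis"],
            k_degradation=h["k_degradation"],
            k_translocation=h["k_translocation"],
            k_nuclear_decay=h["k_nuclear_decay"],
            phase_concentration=h["phase_concentration"],
            basal_transcription=p["basal_transcription"],
            v_transcription=p["v_transcription"],
            k_transcription=p["k_transcription"],
            k_export=p["k_export"],
            k_mrna_decay_nucleus=p["k_mrna_decay_nucleus"],
            k_mrna_decay_cytosol=p["k_mrna_decay_cytosol"],
            k_translation=p["k_translation"],
            k_protein_decay=p["k_protein_decay"],
        )


@dataclass
class GeneRegulationState:
    """Regulation state for one cell and one (generic) gene."""

    hif_cytosol: float = 0.0
    hif_nucleus: float = 0.0
    mrna_nucleus: float = 0.0
    mrna_cytosol: float = 0.0
    protein: float = 0.0

    def __post_init__(self):
        for name, v in self.__dict__.items():
            if v < 0:
                raise RegulationDomainError(f"{name} must be >= 0, got {v}")


def hif_derivatives(
    state: GeneRegulationState,
    o2: float,
    p: RegulationParams,
    v_cytosol: float = 0.33,
    v_nucleus: float = 0.033,
) -> tuple[float, float]:
    """(dHIFc/dt, dHIFn/dt) at the given cytosolic oxygen level.

    At o2 = 0 the PHase degradation term vanishes exactly (the anoxic
    limit of the mass-action law).
    """
    if o2 < 0:
        raise RegulationDomainError(f"o2 must be >= 0, got {o2}")
    syn = p.k_synthesis * p.phase_concentration
    deg = p.k_degradation * p.phase_concentration * o2 * state.hif_cytosol
    tr = p.k_translocation * state.hif_cytosol
    d_hif_c = syn - deg - tr
    d_hif_n = tr * (v_cytosol / v_nucleus) - p.k_nuclear_decay * state.hif_nucleus
    return d_hif_c, d_hif_n


def transcription_rate(hif_nucleus: float, p: RegulationParams) -> float:
    """mRNA synthesis rate: basal plus a saturating HIF-activated term.

    Strictly increasing in nuclear HIF and bounded by basal + V_max.
    """
    if hif_nucleus < 0:
        raise RegulationDomainError(f"hif_nucleus must be >= 0, got {hif_nucleus}")
    return p.basal_transcription + p.v_transcription * hif_nucleus / (
        p.k_transcription + hif_nucleus
    )


def protein_derivatives(
    state: GeneRegulationState,
    p: RegulationParams,
    v_cytosol: float = 0.33,
    v_nucleus: float = 0.033,
) -> tuple[float, float, float]:
    """(dMn/dt, dMc/dt, dP/dt) for the mRNA and protein pools."""
    d_mn = (
        transcription_rate(state.hif_nucleus, p)
        - (p.k_export + p.k_mrna_decay_nucleus) * state.mrna_nucleus
    )
    d_mc = (
        p.k_export * state.mrna_nucleus * (v_nucleus / v_cytosol)
        - p.k_mrna_decay_cytosol * state.mrna_cytosol
    )
    d_p = p.k_translation * state.mrna_cytosol - p.k_protein_decay * state.protein
    return d_mn, d_mc, d_p


def effective_capacity(base_vmax: float, protein: float, protein_ref: float) -> float:
    """Scale an enzyme/transporter capacity linearly with its protein pool.

    Returns ``base_vmax * protein / protein_ref`` clipped below at zero;
    at the normoxic reference level (protein == protein_ref) the base
    capacity is returned unchanged.
    """
    if protein_ref <= 0:
        raise RegulationDomainError(f"protein_ref must be > 0, got {protein_ref}")
    if base_vmax < 0:
        raise RegulationDomainError(f"base_vmax must be >= 0, got {base_vmax}")
    return max(0.0, base_vmax * protein / protein_ref)


def steady_state(
    o2: float,
    p: RegulationParams,
    v_cytosol: float = 0.33,
    v_nucleus: float = 0.033,
) -> GeneRegulationState:
    """Closed-form steady state of the regulation scheme at clamped O2.

    The system is linear once nuclear HIF is known, so the fixed point is
    exact; it doubles as the independent oracle for the ODE integration
    of the same scheme.
    """
    if o2 < 0:
        raise RegulationDomainError(f"o2 must be >= 0, got {o2}")
    syn = p.k_synthesis * p.phase_concentration
    loss = p.k_degradation * p.phase_concentration * o2 + p.k_translocation
    if loss == 0:
        raise RegulationDomainError(
            "HIF has no loss term: steady state undefined"
        )
    hif_c = syn / loss
    hif_n = (
        p.k_translocation * hif_c * (v_cytosol / v_nucleus) / p.k_nuclear_decay
    )
    tx = transcription_rate(hif_n, p)
    mn = tx / (p.k_export + p.k_mrna_decay_nucleus)
    mc = p.k_export * mn * (v_nucleus / v_cytosol) / p.k_mrna_decay_cytosol
    prot = p.k_translation * mc / p.k_protein_decay
    return GeneRegulationState(
        hif_cytosol=hif_c, hif_nucleus=hif_n,
        mrna_nucleus=mn, mrna_cytosol=mc, protein=prot,
    )
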