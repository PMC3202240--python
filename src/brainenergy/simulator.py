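"""ODE assembly, deterministic integration and plateau detection.

The assembler turns a :class:`~brainenergy.model_core.CompartmentalModel`
into a vectorised right-hand side.  Every reaction rate J is in
mM min^-1 referenced to the reaction's source (host) compartment of
volume V_src; a species in compartment C receives the contribution
``±stoich * J * (V_src / V_C)``, so amounts (concentration x volume) are
conserved exactly across compartment boundaries.

The per-gene expression block (transcription, mRNA export/decay,
translation, protein decay) is evaluated through
:mod:`brainenergy.gene_regulation`; regulated reactions read their
effective capacity live from the protein state (linear scaling against
the normoxic reference level).

Integration uses a stiff-capable implicit solver (LSODA) at relative
tolerance 1e-8 / absolute 1e-10 by default; results are reproducible
bit-for-bit at fixed tolerances.  Negative-concentration excursions are
never clipped — violations beyond a 1e-9 band surface as diagnostics so
that conservation checks stay honest.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import gene_regulation
from .model_core import CompartmentalModel, ParameterTable, validate_model

__all__ = [
    "ODESystem",
    "TimeCourse",
    "SteadyStateReport",
    "SimulationError",
    "ModelValidationError",
    "assemble_odes",
    "simulate",
    "detect_steady_state",
    "EPS_SOLVER",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

EPS_SOLVER = 1e-9      # tolerated negative-concentration band, mM
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-10


class SimulationError(RuntimeError):
    pass


class ModelValidationError(ValueError):
    pass


@dataclass
class SteadyStateReport:
    key: str                # "species@compartment"
    attained: bool
    plateau: float | None   # mM, trailing-window mean (final value if not attained)
    attainment_time: float | None  # min
    criterion: str

    def __str__(self):
        if self.attained:
            return (f"{self.key}: plateau {self.plateau:.4g} mM "
                    f"from t = {self.attainment_time:g} min ({self.criterion})")
        return f"{self.key}: no plateau attained ({self.criterion})"


class TimeCourse:
    """Solver output: time grid x species concentrations, plus provenance.

    ``data`` is a DataFrame indexed by time (min) with one column per
    ``species@compartment``.
    """

    def __init__(self, data: pd.DataFrame, metadata: dict,
                 diagnostics: list[str] | None = None):
        if not data.index.is_monotonic_increasing or data.index.duplicated().any():
            raise ValueError("time grid must be strictly increasing")
        self.data = data
        self.metadata = dict(metadata)
        self.diagnostics = list(diagnostics or [])

    @property
    def times(self) -> np.ndarray:
        return self.data.index.to_numpy()

    def series(self, key: str) -> pd.Series:
        if key not in self.data.columns:
            raise KeyError(f"unknown species key {key!r}")
        return self.data[key]

    def final(self, key: str) -> float:
        return float(self.series(key).iloc[-1])

    # ------------------------------------------------------------- CSV I/O
    def to_csv(self, path_or_buf, layout: str = "wide") -> None:
        """Serialise with a ``#``-prefixed metadata header block."""
        header = "".join(
            f"# {k}: {v}\n" for k, v in sorted(self.metadata.items())
        )
        if layout == "wide":
            body = self.data.rename_axis("time_min").reset_index()
        elif layout == "long":
            body = (
                self.data.rename_axis("time_min")
                .reset_index()
                .melt(id_vars="time_min", var_name="species", value_name="mM")
            )
        else:
            raise ValueError(f"unknown layout {layout!r}")
        text = header + body.to_csv(index=False)
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w") as fh:
                fh.write(text)

    @classmethod
    def from_csv(cls, path_or_buf) -> "TimeCourse":
        if hasattr(path_or_buf, "read"):
            text = path_or_buf.read()
        else:
            with open(path_or_buf) as fh:
                text = fh.read()
        meta = {}
        lines = text.splitlines(keepends=True)
        body_start = 0
        for i, line in enumerate(lines):
            if line.startswith("#"):
                k, _, v = line[1:].strip().partition(": ")
                meta[k] = v
                body_start = i + 1
            else:
                break
        df = pd.read_csv(io.StringIO("".join(lines[body_start:])))
        if {"species", "mM"} <= set(df.columns):  # long layout
            df = df.pivot(index="time_min", columns="species", values="mM")
            df.columns.name = None
        else:
            df = df.set_index("time_min")
        df.index.name = None
        return cls(df, meta)


def _provenance_digest(params: ParameterTable) -> str:
    h = hashlib.sha256()
    for e in sorted(params.entries(), key=lambda e: (e.reaction, e.name)):
        h.update(f"{e.reaction}|{e.name}|{e.value!r}|{e.provenance}\n".encode())
    return h.hexdigest()[:16]


class ODESystem:
    """Vectorised derivative function for one model (+ regulation block)."""

    def __init__(self, model: CompartmentalModel):
        report = validate_model(model)
        if not report.ok:
            raise ModelValidationError(
                "refusing to assemble an invalid model:\n" + str(report)
            )
        self.model = model
        keys = [s.key for s in model.species.values()]
        keys.sort()
        self.keys = keys
        self.index = {k: i for i, k in enumerate(keys)}
        self.n = len(keys)
        vols = {cid: c.volume for cid, c in model.compartments.items()}
        self.volumes = vols

        self.y0 = np.zeros(self.n)
        self.clamped = np.zeros(self.n, dtype=bool)
        for s in model.species.values():
            i = self.index[s.key]
            self.y0[i] = s.initial_concentration
            self.clamped[i] = s.clamped
        self.carbon = np.zeros(self.n)
        self.volume_of = np.zeros(self.n)
        for s in model.species.values():
            i = self.index[s.key]
            self.carbon[i] = s.carbon
            self.volume_of[i] = vols[s.compartment]

        self._build_reaction_groups()
        self._build_regulation()

    # -------------------------------------------------------------- assembly
    def _idx(self, sp: str, comp: str) -> int:
        return self.index[f"{sp}@{comp}"]

    def _build_reaction_groups(self):
        model = self.model
        vols = self.volumes
        m = len(model.reactions)
        self.reaction_numbers = np.array([r.number for r in model.reactions])
        # scatter matrix S: dy = S @ rates
        rows, cols, vals = [], [], []
        for j, r in enumerate(model.reactions):
            v_src = vols[r.source_compartment]
            for sp, comp, st in r.substrates:
                rows.append(self._idx(sp, comp))
                cols.append(j)
                vals.append(-st * v_src / vols[comp])
            for sp, comp, st in r.products:
                rows.append(self._idx(sp, comp))
                cols.append(j)
                vals.append(+st * v_src / vols[comp])
        from scipy.sparse import coo_matrix

        self.S = coo_matrix(
            (vals, (rows, cols)), shape=(self.n, m)
        ).tocsr()

        # per-form index/parameter arrays
        g = {
            "pd": {"ix": [], "iy": [], "gamma": [], "sigma": [], "j": []},
            "ft": {"ix": [], "v": [], "km": [], "j": []},
            "mm": {"ix": [], "vmax": [], "km": [], "j": []},
            "bi": {"ix": [], "iy": [], "jmax": [], "k": [], "j": []},
            "ma": {"idx": [], "k": [], "j": []},
            "ui": {"ix": [], "ii": [], "vmax": [], "km": [], "ki": [], "j": []},
        }
        for j, r in enumerate(model.reactions):
            p = r.law.params
            form = r.law.form
            if form == "passive_diffusion":
                (sx, cx), (sy, cy) = r.rate_species
                g["pd"]["ix"].append(self._idx(sx, cx))
                g["pd"]["iy"].append(self._idx(sy, cy))
                g["pd"]["gamma"].append(p["gamma"])
                g["pd"]["sigma"].append(p["sigma"])
                g["pd"]["j"].append(j)
            elif form == "facilitated_transport":
                (sx, cx) = r.rate_species[0]
                g["ft"]["ix"].append(self._idx(sx, cx))
                g["ft"]["v"].append(p["v"])
                g["ft"]["km"].append(p["km"])
                g["ft"]["j"].append(j)
            elif form == "michaelis_menten":
                (sx, cx) = r.rate_species[0]
                g["mm"]["ix"].append(self._idx(sx, cx))
                g["mm"]["vmax"].append(p["v_max"])
                g["mm"]["km"].append(p["km"])
                g["mm"]["j"].append(j)
            elif form == "bimolecular_mm":
                (sx, cx), (sy, cy) = r.rate_species
                g["bi"]["ix"].append(self._idx(sx, cx))
                g["bi"]["iy"].append(self._idx(sy, cy))
                g["bi"]["jmax"].append(p["j_max"])
                g["bi"]["k"].append(p["k"])
                g["bi"]["j"].append(j)
            elif form == "mass_action":
                idx = [self._idx(sp, comp) for sp, comp in r.rate_species]
                while len(idx) < 3:  # pad with the virtual ones-slot
                    idx.append(self.n)
                g["ma"]["idx"].append(idx[:3])
                g["ma"]["k"].append(p["k"])
                g["ma"]["j"].append(j)
            elif form == "uncompetitive_inhibition":
                (sx, cx) = r.rate_species[0]
                g["ui"]["ix"].append(self._idx(sx, cx))
                g["ui"]["ii"].append(self._idx(*r.inhibitor))
                g["ui"]["vmax"].append(p["v_max"])
                g["ui"]["km"].append(p["km"])
                g["ui"]["ki"].append(p["ki"])
                g["ui"]["j"].append(j)
        self.groups = {
            form: {k: np.asarray(v) for k, v in d.items()}
            for form, d in g.items()
        }

    def _cell_of_reaction(self, r) -> str | None:
        comps = r.compartments()
        if comps & {"Nc", "Nn", "Nm"}:
            return "neuron"
        if comps & {"Ac", "An", "Am"}:
            return "astrocyte"
        return None

    def _build_regulation(self):
        model = self.model
        reg = model.regulation
        m = len(model.reactions)
        if not reg:  # regulation-free model (test/toy networks)
            self.reg_params = None
            self.genes = []
            self.cells = {}
            self.protein_ref = {}
            self.reg_prot_idx = np.full(m, -1, dtype=int)
            self.reg_prot_ref = np.ones(m)
            empty = np.array([], dtype=int)
            self.expr_mn = self.expr_mc = self.expr_pr = self.expr_hn = empty
            self.expr_vc = self.expr_vn = np.array([], dtype=float)
            return
        self.reg_params = gene_regulation.RegulationParams.from_config(reg)
        self.genes = list(model.genes)
        cells = reg["cells"]
        self.cells = cells
        self.protein_ref = {}
        for cell, locs in cells.items():
            ss = gene_regulation.steady_state(
                reg["o2_reference"], self.reg_params,
                v_cytosol=self.volumes[locs["cytosol"]],
                v_nucleus=self.volumes[locs["nucleus"]],
            )
            self.protein_ref[cell] = ss.protein

        # regulated-reaction capacity multiplier indices
        m = len(model.reactions)
        self.reg_prot_idx = np.full(m, -1, dtype=int)
        self.reg_prot_ref = np.ones(m)
        for j, r in enumerate(model.reactions):
            if r.regulated_by is None:
                continue
            cell = self._cell_of_reaction(r)
            if cell is None:
                continue
            cyt = cells[cell]["cytosol"]
            self.reg_prot_idx[j] = self._idx(f"prot_{r.regulated_by}", cyt)
            self.reg_prot_ref[j] = self.protein_ref[cell]

        # expression-block index arrays over (cell x gene)
        mn, mc, pr, hn, vc, vn = [], [], [], [], [], []
        for cell, locs in cells.items():
            cyt, nuc = locs["cytosol"], locs["nucleus"]
            for gene in self.genes:
                mn.append(self._idx(f"mRNA_{gene}", nuc))
                mc.append(self._idx(f"mRNA_{gene}", cyt))
                pr.append(self._idx(f"prot_{gene}", cyt))
                hn.append(self._idx("HIF", nuc))
                vc.append(self.volumes[cyt])
                vn.append(self.volumes[nuc])
        self.expr_mn = np.array(mn)
        self.expr_mc = np.array(mc)
        self.expr_pr = np.array(pr)
        self.expr_hn = np.array(hn)
        self.expr_vc = np.array(vc, dtype=float)
        self.expr_vn = np.array(vn, dtype=float)

    # ------------------------------------------------------------------ rates
    def reaction_rates(self, y: np.ndarray) -> np.ndarray:
        """Instantaneous rates (mM/min, source-compartment referenced) for
        every reaction, in catalogue order."""
        yext = np.append(y, 1.0)  # virtual ones-slot for short mass-action laws
        rates = np.zeros(len(self.model.reactions))
        g = self.groups
        if len(g["pd"]["j"]):
            d = g["pd"]
            rates[d["j"]] = d["gamma"] * (y[d["ix"]] - d["sigma"] * y[d["iy"]])
        if len(g["ft"]["j"]):
            d = g["ft"]
            c = y[d["ix"]]
            rates[d["j"]] = d["v"] * c / (d["km"] + c)
        if len(g["mm"]["j"]):
            d = g["mm"]
            c = y[d["ix"]]
            rates[d["j"]] = d["vmax"] * c / (d["km"] + c)
        if len(g["bi"]["j"]):
            d = g["bi"]
            prod = y[d["ix"]] * y[d["iy"]]
            rates[d["j"]] = d["jmax"] * prod / (d["k"] + prod)
        if len(g["ma"]["j"]):
            d = g["ma"]
            idx = d["idx"]
            rates[d["j"]] = (
                d["k"] * yext[idx[:, 0]] * yext[idx[:, 1]] * yext[idx[:, 2]]
            )
        if len(g["ui"]["j"]):
            d = g["ui"]
            s, i = y[d["ix"]], y[d["ii"]]
            rates[d["j"]] = d["vmax"] * s / (d["km"] + s * (1.0 + i / d["ki"]))
        # live capacity scaling from the gene-regulation protein state
        sel = self.reg_prot_idx >= 0
        if sel.any():
            mult = np.maximum(0.0, y[self.reg_prot_idx[sel]] / self.reg_prot_ref[sel])
            rates[sel] *= mult
        return rates

    def expression_derivatives(self, y: np.ndarray) -> np.ndarray:
        """Expression-block contribution (mRNA/protein pools) to dy."""
        dy = np.zeros(self.n)
        if self.reg_params is None or len(self.expr_mn) == 0:
            return dy
        p = self.reg_params
        hn = y[self.expr_hn]
        mn = y[self.expr_mn]
        mc = y[self.expr_mc]
        pr = y[self.expr_pr]
        tx = p.basal_transcription + p.v_transcription * hn / (p.k_transcription + hn)
        d_mn = tx - (p.k_export + p.k_mrna_decay_nucleus) * mn
        d_mc = p.k_export * mn * (self.expr_vn / self.expr_vc) - p.k_mrna_decay_cytosol * mc
        d_pr = p.k_translation * mc - p.k_protein_decay * pr
        np.add.at(dy, self.expr_mn, d_mn)
        np.add.at(dy, self.expr_mc, d_mc)
        np.add.at(dy, self.expr_pr, d_pr)
        return dy

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = self.S @ self.reaction_rates(y)
        dy += self.expression_derivatives(y)
        dy[self.clamped] = 0.0
        return dy

    # --------------------------------------------------------- conservation
    def carbon_amount(self, y: np.ndarray) -> float:
        """Total carbon amount (mmol) across all compartments."""
        return float(np.sum(self.carbon * y * self.volume_of))


def assemble_odes(model: CompartmentalModel) -> ODESystem:
    """Assemble the coupled metabolic + regulation ODE system.

    Raises :class:`ModelValidationError` for a model whose validation
    report is non-empty.
    """
    return ODESystem(model)


def simulate(
    model: CompartmentalModel,
    scenario=None,
    t_end: float = 250.0,
    output_step: float = 1.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    params: ParameterTable | None = None,
    system: ODESystem | None = None,
) -> TimeCourse:
    """Deterministic stiff time-course integration on a dense output grid.

    ``scenario`` (see :mod:`brainenergy.scenarios`) sets the blood
    boundary conditions: blood O2 is clamped for the whole run; blood
    glucose is clamped only when the scenario says so (glucose
    starvation).
    """
    if t_end <= 0:
        raise ValueError("t_end must be > 0")
    sys_ = system if system is not None else assemble_odes(model)
    y0 = sys_.y0.copy()
    clamped = sys_.clamped.copy()

    meta = {
        "model_variant": model.variant,
        "solver": "LSODA",
        "rtol": rtol,
        "atol": atol,
        "t_end_min": t_end,
        "output_step_min": output_step,
    }
    if params is not None:
        meta["parameter_digest"] = _provenance_digest(params)
    if scenario is not None:
        i_glc = sys_.index["Glc@b"]
        i_o2 = sys_.index["O2@b"]
        y0[i_glc] = scenario.blood_glucose
        y0[i_o2] = scenario.blood_o2
        clamped[i_o2] = True  # blood O2 always clamped
        if scenario.glucose_clamped:
            clamped[i_glc] = True
        meta.update(
            scenario=scenario.name,
            blood_glucose_mM=scenario.blood_glucose,
            blood_glucose_clamped=scenario.glucose_clamped,
            blood_o2_mM=scenario.blood_o2,
        )
        if scenario.extrapolation:
            meta["extrapolation"] = True

    def rhs(t, y):
        dy = sys_.S @ sys_.reaction_rates(y)
        dy += sys_.expression_derivatives(y)
        dy[clamped] = 0.0
        return dy

    n_steps = int(round(t_end / output_step))
    t_eval = np.linspace(0.0, t_end, n_steps + 1)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0, method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"integrator failed at t = {sol.t[-1] if len(sol.t) else 0.0:.3f} min: "
            f"{sol.message}"
        )
    meta["n_rhs_evaluations"] = int(sol.nfev)

    diagnostics = []
    ymin = sol.y.min(axis=1)
    for i in np.where(ymin < -EPS_SOLVER)[0]:
        diagnostics.append(
            f"negative concentration excursion: {sys_.keys[i]} "
            f"reached {ymin[i]:.3e} mM"
        )

    data = pd.DataFrame(sol.y.T, index=sol.t, columns=sys_.keys)
    return TimeCourse(data, meta, diagnostics)


def detect_steady_state(
    tc: TimeCourse,
    key: str,
    window: float = 30.0,
    rel_tol: float = 0.01,
) -> SteadyStateReport:
    """Trailing-window plateau detection.

    The plateau value is the mean over the trailing ``window`` minutes;
    the attainment time is the earliest grid time after which the
    trajectory stays within ``rel_tol`` (relative, with a 1e-12 absolute
    floor for zero plateaus) of that value.  A series that never settles
    is reported as not attained, not raised.
    """
    series = tc.series(key)
    t = series.index.to_numpy(dtype=float)
    c = series.to_numpy(dtype=float)
    span = t[-1] - t[0]
    if window >= span:
        raise ValueError("window must be shorter than the trajectory span")
    criterion = f"trailing {window:g} min within {rel_tol:g} relative"
    tail = t >= t[-1] - window
    plateau = float(c[tail].mean())
    tol = rel_tol * max(abs(plateau), 1e-12)
    dev_ok = np.abs(c - plateau) <= tol
    # earliest index from which every later sample is within tolerance
    ok_from_here = np.logical_and.accumulate(dev_ok[::-1])[::-1]
    if not ok_from_here[tail].all():
        return SteadyStateReport(key, False, float(c[-1]), None, criterion)
    first = int(np.argmax(ok_from_here))
    return SteadyStateReport(key, True, plateau, float(t[first]), criterion)
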