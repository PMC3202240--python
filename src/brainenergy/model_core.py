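"""Declarative construction and validation of the two model variants.

The reaction network (94 numbered reactions) lives in shipped YAML
configuration; each model variant is a table-driven selection of reaction
numbers from that catalogue, so the classical view and the
astrocyte-neuron lactate shuttle (ANLSH) differ only in membership, never
in hard-coded topology.  The classical model carries reactions 1-92; the
ANLSH model drops the neuronal glycolysis block and the entire astrocyte
aerobic block (there are no reactions located in the astrocyte
mitochondrion, Am) and adds the two shuttle-specific reactions 93-94
(neuron MCT2 lactate uptake and neuron LDH1 lactate oxidation).

Compartments (relative volumes, litres): Nn 0.033, Nc 0.33, Nm 0.0855,
An 0.019, Ac 0.19, Am 0.0475, e 0.2, b 0.095.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .kinetics import LAW_FORMS, LAW_PARAMS

__all__ = [
    "Compartment",
    "Species",
    "KineticLaw",
    "Reaction",
    "CompartmentalModel",
    "ParameterTable",
    "ParameterEntry",
    "ParameterResolutionError",
    "ConfigError",
    "ValidationReport",
    "load_parameters",
    "default_parameters",
    "build_classical_model",
    "build_anlsh_model",
    "build_model",
    "validate_model",
]

COMPARTMENT_IDS = ("Nn", "Nc", "Nm", "An", "Ac", "Am", "e", "b")

#: recognized units for parameter entries
_KNOWN_UNITS = {
    "mM", "mM/min", "1/min", "dimensionless", "mM^2", "L",
    "1/(mM*min)", "1/(mM^2*min)",
}

PROVENANCE_TAGS = ("supplementary", "literature_default", "estimated")

#: cofactor pairs that must interconvert 1:1 within any single reaction
_CONSERVED_PAIRS = (("NAD", "NADH"), ("FAD", "FADH2"), ("ATP", "ADP"), ("Cr", "PCr"))


class ConfigError(ValueError):
    """Raised for malformed or inconsistent configuration input."""


class ParameterResolutionError(KeyError):
    """A kinetic parameter referenced by the model cannot be resolved."""


@dataclass(frozen=True)
class Compartment:
    id: str
    description: str
    volume: float  # litres (relative volumes)

    def __post_init__(self):
        if self.volume <= 0:
            raise ConfigError(f"compartment {self.id}: volume must be > 0")


@dataclass(frozen=True)
class Species:
    id: str
    compartment: str
    initial_concentration: float  # mM
    clamped: bool = False
    carbon: int = 0

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise ConfigError(
                f"species {self.key}: initial concentration must be >= 0"
            )

    @property
    def key(self) -> str:
        return f"{self.id}@{self.compartment}"


@dataclass(frozen=True)
class KineticLaw:
    form: str
    params: Mapping[str, float]

    def __post_init__(self):
        if self.form not in LAW_FORMS:
            raise ConfigError(f"unknown kinetic-law form {self.form!r}")

    def required_params(self) -> tuple[str, ...]:
        return LAW_PARAMS[self.form]


@dataclass(frozen=True)
class Reaction:
    """One numbered reaction of the catalogue.

    ``substrates``/``products`` are tuples of ``(species id, compartment
    id, stoichiometry)``.  ``rate_species`` lists the (species,
    compartment) pairs the rate law reads, in law-specific order; species
    appearing there but not among the substrates act as modifiers.  The
    rate is referenced to ``source_compartment`` (the host compartment
    for in-place reactions).
    """

    number: int
    name: str
    substrates: tuple[tuple[str, str, float], ...]
    products: tuple[tuple[str, str, float], ...]
    law: KineticLaw
    source_compartment: str
    target_compartment: str | None = None
    rate_species: tuple[tuple[str, str], ...] = ()
    inhibitor: tuple[str, str] | None = None
    regulated_by: str | None = None

    def __post_init__(self):
        for _, _, st in (*self.substrates, *self.products):
            if st <= 0:
                raise ConfigError(f"reaction {self.number}: stoichiometries must be positive")
        if self.target_compartment is not None and (
            self.target_compartment == self.source_compartment
        ):
            raise ConfigError(
                f"reaction {self.number}: transport requires source != target"
            )

    @property
    def is_transport(self) -> bool:
        return self.target_compartment is not None

    @property
    def modifiers(self) -> tuple[tuple[str, str], ...]:
        subs = {(s, c) for s, c, _ in self.substrates}
        return tuple((s, c) for s, c in self.rate_species if (s, c) not in subs)

    def compartments(self) -> set[str]:
        out = {c for _, c, _ in (*self.substrates, *self.products)}
        out.add(self.source_compartment)
        if self.target_compartment:
            out.add(self.target_compartment)
        out.update(c for _, c in self.rate_species)
        return out


@dataclass(frozen=True)
class ParameterEntry:
    reaction: int
    name: str
    value: float
    unit: str
    provenance: str

    def __post_init__(self):
        if self.unit not in _KNOWN_UNITS:
            raise ConfigError(
                f"parameter ({self.reaction}, {self.name!r}): unknown unit {self.unit!r}"
            )
        if self.provenance not in PROVENANCE_TAGS:
            raise ConfigError(
                f"parameter ({self.reaction}, {self.name!r}): unknown provenance "
                f"{self.provenance!r}"
            )
        if not (self.value == self.value) or self.value in (float("inf"), float("-inf")):
            raise ConfigError(
                f"parameter ({self.reaction}, {self.name!r}): value must be finite"
            )
        if self.value < 0:
            raise ConfigError(
                f"parameter ({self.reaction}, {self.name!r}): rate/affinity "
                f"parameters must be >= 0, got {self.value}"
            )


class ParameterTable:
    """Kinetic parameters keyed by (reaction number, parameter name),
    plus initial concentrations and the always-clamped species list."""

    def __init__(
        self,
        entries: Iterable[ParameterEntry],
        initial_concentrations: Mapping[str, Mapping[str, float]],
        always_clamped: Iterable[str] = (),
    ):
        self._entries: dict[tuple[int, str], ParameterEntry] = {}
        for e in entries:
            key = (e.reaction, e.name)
            if key in self._entries:
                raise ConfigError(f"duplicate parameter key {key}")
            self._entries[key] = e
        self.initial_concentrations = {
            comp: dict(vals) for comp, vals in initial_concentrations.items()
        }
        for comp, vals in self.initial_concentrations.items():
            for sp, v in vals.items():
                if v < 0:
                    raise ConfigError(
                        f"initial concentration {sp}@{comp} must be >= 0, got {v}"
                    )
        self.always_clamped = tuple(always_clamped)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[int, str]) -> bool:
        return key in self._entries

    def entries(self) -> list[ParameterEntry]:
        return list(self._entries.values())

    def get(self, reaction: int, name: str) -> ParameterEntry:
        try:
            return self._entries[(reaction, name)]
        except KeyError:
            raise ParameterResolutionError(
                f"no parameter entry for reaction {reaction}, parameter {name!r}"
            ) from None

    def value(self, reaction: int, name: str) -> float:
        return self.get(reaction, name).value

    def initial(self, species: str, compartment: str) -> float:
        comp = self.initial_concentrations.get(compartment, {})
        if species not in comp:
            raise ParameterResolutionError(
                f"no initial concentration for {species}@{compartment}"
            )
        return comp[species]

    def copy(self) -> "ParameterTable":
        return ParameterTable(
            self.entries(),
            copy.deepcopy(self.initial_concentrations),
            self.always_clamped,
        )

    def with_entry(self, reaction: int, name: str, value: float,
                   unit: str | None = None,
                   provenance: str = "estimated") -> "ParameterTable":
        """Return a copy with one entry replaced/added (functional update)."""
        new = self.copy()
        old = new._entries.get((reaction, name))
        if unit is None:
            if old is None:
                raise ConfigError("unit required for a new parameter entry")
            unit = old.unit
        new._entries[(reaction, name)] = ParameterEntry(
            reaction, name, value, unit, provenance
        )
        return new

    def without(self, reaction: int, name: str) -> "ParameterTable":
        new = self.copy()
        new._entries.pop((reaction, name), None)
        return new


def _data_text(name: str) -> str:
    return resources.files("brainenergy.data").joinpath(name).read_text()


def load_parameters(source: str) -> ParameterTable:
    """Parse a structured-config (YAML) text into a :class:`ParameterTable`.

    Each entry must declare value, unit and provenance; negative values,
    unknown units and duplicate keys are rejected with the offending key
    named.
    """
    try:
        doc = yaml.safe_load(source)
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse parameter config: {exc}") from exc
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ConfigError("parameter config must contain a 'parameters' list")
    entries = [
        ParameterEntry(
            reaction=int(p["reaction"]),
            name=str(p["name"]),
            value=float(p["value"]),
            unit=str(p.get("unit", "")),
            provenance=str(p.get("provenance", "estimated")),
        )
        for p in doc["parameters"]
    ]
    return ParameterTable(
        entries,
        doc.get("initial_concentrations", {}),
        doc.get("always_clamped", ()),
    )


def default_parameters() -> ParameterTable:
    """The shipped parameter table (literature-lineage defaults)."""
    return load_parameters(_data_text("parameters.yaml"))


def load_compartments() -> dict[str, Compartment]:
    doc = yaml.safe_load(_data_text("compartments.yaml"))
    return {
        cid: Compartment(cid, spec["description"], float(spec["volume"]))
        for cid, spec in doc["compartments"].items()
    }


def _load_catalogue() -> tuple[list[dict], dict[str, int]]:
    doc = yaml.safe_load(_data_text("network.yaml"))
    return doc["reactions"], {k: int(v) for k, v in doc["species_carbons"].items()}


def _parse_rate_species(spec_list, host: str) -> tuple[tuple[str, str], ...]:
    out = []
    for item in spec_list:
        if "@" in item:
            sp, comp = item.split("@", 1)
        else:
            sp, comp = item, host
        out.append((sp, comp))
    return tuple(out)


def _reaction_from_config(raw: dict, params: ParameterTable) -> Reaction:
    num = int(raw["number"])
    law_form = raw["law"]
    law_params = {}
    for pname in LAW_PARAMS[law_form]:
        law_params[pname] = params.value(num, pname)
    law = KineticLaw(law_form, law_params)

    if "species" in raw:  # transport shorthand
        sp, src, dst = raw["species"], raw["source"], raw["target"]
        substrates = ((sp, src, 1.0),)
        products = ((sp, dst, 1.0),)
        rate_species = ((sp, src),) if law_form != "passive_diffusion" else (
            (sp, src), (sp, dst))
        return Reaction(
            number=num, name=raw["name"], substrates=substrates,
            products=products, law=law, source_compartment=src,
            target_compartment=dst, rate_species=rate_species,
            regulated_by=raw.get("regulated_by"),
        )

    host = raw["compartment"]
    def parse_side(side):
        out = []
        for item in raw.get(side, []):
            out.append((item["species"], item.get("compartment", host),
                        float(item["stoich"])))
        return tuple(out)

    substrates, products = parse_side("substrates"), parse_side("products")
    rate_species = _parse_rate_species(raw.get("rate_species", []), host)
    inhibitor = None
    if raw.get("inhibitor"):
        item = raw["inhibitor"]
        inhibitor = (item, host) if "@" not in item else tuple(item.split("@", 1))
    # cross-compartment enzymatic steps (e.g. the NADH shuttle) have no
    # single target; transport flag only applies to the shorthand form
    return Reaction(
        number=num, name=raw["name"], substrates=substrates, products=products,
        law=law, source_compartment=host, rate_species=rate_species,
        inhibitor=inhibitor, regulated_by=raw.get("regulated_by"),
    )


@dataclass
class CompartmentalModel:
    variant: str  # classical | anlsh
    compartments: dict[str, Compartment]
    species: dict[tuple[str, str], Species]  # (id, compartment) -> Species
    reactions: list[Reaction]
    genes: tuple[str, ...]
    regulation: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)

    def reaction(self, number: int) -> Reaction:
        for r in self.reactions:
            if r.number == number:
                return r
        raise KeyError(f"no reaction numbered {number} in the {self.variant} model")

    @property
    def reaction_numbers(self) -> list[int]:
        return [r.number for r in self.reactions]

    def species_in(self, compartment: str) -> list[Species]:
        return [s for s in self.species.values() if s.compartment == compartment]


def _regulation_config() -> dict:
    return yaml.safe_load(_data_text("regulation.yaml"))


def _variant_config(variant: str) -> dict:
    return yaml.safe_load(_data_text(f"model_{variant}.yaml"))


def build_model(
    variant: str,
    params: ParameterTable | None = None,
    options: Mapping | None = None,
) -> CompartmentalModel:
    """Build one model variant from the shipped catalogue and ``params``.

    Membership is table-driven: the variant file lists the reaction
    numbers it contains.  The ``neuron_glucose_uptake`` option re-enables
    the neuronal glucose-uptake reactions in the ANLSH variant.
    """
    if params is None:
        params = default_parameters()
    cfg = _variant_config(variant)
    opts = dict(cfg.get("options", {}))
    if options:
        opts.update(options)
    numbers = set(int(n) for n in cfg["reactions"])
    if opts.get("neuron_glucose_uptake"):
        numbers.update(int(n) for n in opts.get("neuron_glucose_reactions", ()))

    catalogue, carbons = _load_catalogue()
    compartments = load_compartments()
    reactions = [
        _reaction_from_config(raw, params)
        for raw in catalogue
        if int(raw["number"]) in numbers
    ]
    missing = numbers - {r.number for r in reactions}
    if missing:
        raise ConfigError(f"variant {variant} lists unknown reactions {sorted(missing)}")
    reactions.sort(key=lambda r: r.number)

    reg_cfg = _regulation_config()
    genes = tuple(reg_cfg["genes"])

    clamped = set(params.always_clamped)
    species: dict[tuple[str, str], Species] = {}

    def add_species(sp: str, comp: str, conc: float | None = None):
        key = (sp, comp)
        if key in species:
            return
        if conc is None:
            conc = params.initial(sp, comp)
        species[key] = Species(
            id=sp, compartment=comp, initial_concentration=conc,
            clamped=f"{sp}@{comp}" in clamped, carbon=carbons.get(sp, 0),
        )

    # regulation species first (HIF pools are referenced by the sensor
    # reactions), initialised at the normoxic reference steady state so
    # normoxic effective capacities equal base V_max
    from . import gene_regulation  # deferred: avoids import cycle

    reg_params = gene_regulation.RegulationParams.from_config(reg_cfg)
    volumes = {cid: c.volume for cid, c in compartments.items()}
    for cell, locs in reg_cfg["cells"].items():
        cyt, nuc = locs["cytosol"], locs["nucleus"]
        ss = gene_regulation.steady_state(
            reg_cfg["o2_reference"], reg_params,
            v_cytosol=volumes[cyt], v_nucleus=volumes[nuc],
        )
        add_species("HIF", cyt, ss.hif_cytosol)
        add_species("HIF", nuc, ss.hif_nucleus)
        for gene in genes:
            add_species(f"mRNA_{gene}", nuc, ss.mrna_nucleus)
            add_species(f"mRNA_{gene}", cyt, ss.mrna_cytosol)
            add_species(f"prot_{gene}", cyt, ss.protein)

    for r in reactions:
        for sp, comp, _ in (*r.substrates, *r.products):
            add_species(sp, comp)
        for sp, comp in r.rate_species:
            add_species(sp, comp)
        if r.inhibitor:
            add_species(*r.inhibitor)

    return CompartmentalModel(
        variant=variant,
        compartments=compartments,
        species=species,
        reactions=reactions,
        genes=genes,
        regulation=reg_cfg,
        options=opts,
    )


def build_classical_model(params: ParameterTable | None = None) -> CompartmentalModel:
    """The classical-view model: both cells run glycolysis and oxidative
    phosphorylation (reactions 1-92)."""
    return build_model("classical", params)


def build_anlsh_model(params: ParameterTable | None = None,
                      options: Mapping | None = None) -> CompartmentalModel:
    """The astrocyte-neuron lactate-shuttle model: astrocyte glycolysis to
    lactate only, neuronal lactate oxidation (no Am reactions; adds 93-94)."""
    return build_model("anlsh", params, options)


@dataclass
class ValidationReport:
    dangling_species: list[str] = field(default_factory=list)
    unreferenced_parameters: list[str] = field(default_factory=list)
    carbon_imbalance: list[str] = field(default_factory=list)
    cofactor_imbalance: list[str] = field(default_factory=list)
    law_parameter_mismatch: list[str] = field(default_factory=list)
    other: list[str] = field(default_factory=list)

    @property
    def issues(self) -> list[str]:
        return (
            self.dangling_species + self.unreferenced_parameters
            + self.carbon_imbalance + self.cofactor_imbalance
            + self.law_parameter_mismatch + self.other
        )

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        return "model OK" if self.ok else "\n".join(self.issues)


def validate_model(model: CompartmentalModel,
                   params: ParameterTable | None = None) -> ValidationReport:
    """Diagnostics: dangling species, per-reaction carbon balance,
    cofactor-pair (redox/phosphate) balance, and kinetic-law parameter
    completeness.  Returns a report, never raises."""
    rep = ValidationReport()
    declared = set(model.species)

    carbons = {
        (s.id, s.compartment): s.carbon for s in model.species.values()
    }

    for r in model.reactions:
        for sp, comp, _ in (*r.substrates, *r.products):
            if (sp, comp) not in declared:
                rep.dangling_species.append(
                    f"reaction {r.number}: references undeclared species {sp}@{comp}"
                )
        for sp, comp in r.rate_species:
            if (sp, comp) not in declared:
                rep.dangling_species.append(
                    f"reaction {r.number}: rate reads undeclared species {sp}@{comp}"
                )
        if comp_missing := [c for c in r.compartments() if c not in model.compartments]:
            rep.other.append(
                f"reaction {r.number}: unknown compartments {comp_missing}"
            )

        # carbon balance (uses per-species carbon counts)
        c_in = sum(carbons.get((sp, c), 0) * st for sp, c, st in r.substrates)
        c_out = sum(carbons.get((sp, c), 0) * st for sp, c, st in r.products)
        if abs(c_in - c_out) > 1e-9:
            rep.carbon_imbalance.append(
                f"reaction {r.number}: carbon imbalance "
                f"({c_in} in, {c_out} out)"
            )

        # conserved-pair balance: NAD/NADH etc. must interconvert 1:1
        def tot(side, name):
            return sum(st for sp, _, st in side if sp == name)
        for a, b_ in _CONSERVED_PAIRS:
            consumed = tot(r.substrates, a) + tot(r.substrates, b_)
            produced = tot(r.products, a) + tot(r.products, b_)
            if abs(consumed - produced) > 1e-9:
                rep.cofactor_imbalance.append(
                    f"reaction {r.number}: {a}/{b_} pool not conserved "
                    f"({consumed} consumed, {produced} produced)"
                )

        required = set(r.law.required_params())
        present = set(r.law.params)
        if required != present:
            rep.law_parameter_mismatch.append(
                f"reaction {r.number}: law {r.law.form} expects parameters "
                f"{sorted(required)}, has {sorted(present)}"
            )

    if params is not None:
        in_model = {r.number: set(r.law.required_params()) for r in model.reactions}
        for e in params.entries():
            if e.reaction in in_model and e.name not in in_model[e.reaction]:
                rep.unreferenced_parameters.append(
                    f"parameter ({e.reaction}, {e.name!r}) is not used by its "
                    f"reaction's kinetic law"
                )

    return rep
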