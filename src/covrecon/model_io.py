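"""Readers for genome-scale metabolic models and reaction databases.

Everything funnels into one normalized :class:`MetabolicModel` holding
metabolites, reactions (signed stoichiometry, reversibility, gene
links), regardless of whether the source was an SBML file, a BIGG-style
JSON model, or cached KEGG flat-file reaction records filtered to one
organism's enzyme complement.  ModelSEED thermodynamics and
expression-based reaction trimming attach to the same representation.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

log = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ReactionThermo",
    "SideMetaboliteList",
    "MetaboliteMapping",
    "MappingError",
    "read_genome_scale_model",
    "write_genome_scale_model",
    "read_kegg_model",
    "read_modelseed_thermo",
    "trim_by_expression",
    "map_metabolites",
    "default_side_metabolites",
    "DEFAULT_COMPARTMENT_PATTERN",
]

# strips BIGG-style trailing compartment tags: glc__D_c -> glc__D, atp[m] -> atp
DEFAULT_COMPARTMENT_PATTERN = r"(_[a-z][a-z0-9]?|\[[a-z]\])$"

MODELSEED_MISSING_DG = 10000000.0


class ReactionSource(str, Enum):
    BIGG = "BIGG"
    KEGG = "KEGG"
    CUSTOM = "custom"


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    xrefs: dict[str, str] = field(default_factory=dict)

    def base_id(self, pattern: str = DEFAULT_COMPARTMENT_PATTERN) -> str:
        return re.sub(pattern, "", self.id)


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]   # metabolite id -> signed coeff, negative = substrate
    reversible: bool = False
    gene_association: list[str] = field(default_factory=list)
    source: ReactionSource = ReactionSource.CUSTOM
    name: str = ""

    def __post_init__(self) -> None:
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ValueError(f"reaction {self.id}: zero stoichiometric coefficient")
        if not self.substrates() or not self.products():
            raise ValueError(f"reaction {self.id}: needs at least one substrate and one product")

    def substrates(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c < 0]

    def products(self) -> list[str]:
        return [m for m, c in self.stoichiometry.items() if c > 0]


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    organism: str = ""
    id: str = "model"

    def __post_init__(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate metabolite ids")
        known = set(ids)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ValueError(f"reaction {r.id} references undeclared species {sorted(missing)}")

    def metabolite(self, mid: str) -> Metabolite:
        return next(m for m in self.metabolites if m.id == mid)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]


@dataclass
class ReactionThermo:
    reaction_id: str
    delta_g: float | None = None          # kcal/mol
    direction_hint: str = "unknown"       # forward | reverse | reversible | unknown


@dataclass
class SideMetaboliteList:
    """Currency metabolites excluded from pathway search (base ids)."""

    ids: set[str]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("side-metabolite list must not be empty")

    @classmethod
    def from_file(cls, path) -> "SideMetaboliteList":
        ids = {line.strip().lower() for line in Path(path).read_text().splitlines()
               if line.strip() and not line.startswith("#")}
        return cls(ids=ids)


def default_side_metabolites() -> SideMetaboliteList:
    path = Path(__file__).parent / "data" / "side_metabolites.txt"
    return SideMetaboliteList.from_file(path)


@dataclass
class MetaboliteMapping:
    """Dataset metabolite name -> one or more model metabolite ids."""

    table: dict[str, list[str]]

    @classmethod
    def from_tsv(cls, path) -> "MetaboliteMapping":
        table: dict[str, list[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            name, ids = line.split("\t")[:2]
            table[name.strip()] = [i.strip() for i in ids.split("|") if i.strip()]
        return cls(table=table)


class MappingError(KeyError):
    def __init__(self, misses: list[str]):
        self.misses = misses
        super().__init__(f"unmapped metabolite names: {', '.join(misses)}")


# ---------------------------------------------------------------------------
# genome-scale model I/O

def read_genome_scale_model(path, format: str | None = None) -> MetabolicModel:
    """Read an SBML or BIGG-style JSON genome-scale model.

    Reversibility comes from the SBML ``reversible`` attribute, or from
    ``lower_bound < 0`` in the BIGG JSON dialect.
    """
    path = Path(path)
    if format is None:
        format = "bigg_json" if path.suffix == ".json" else "sbml"
    if format == "sbml":
        return _read_sbml(path)
    if format == "bigg_json":
        return _read_bigg_json(path)
    raise ValueError(f"unknown model format {format!r}")


def _read_sbml(path: Path) -> MetabolicModel:
    import libsbml

    doc = libsbml.readSBML(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getError(0)
        raise ValueError(
            f"SBML parse error in {path} at line {err.getLine()}: {err.getMessage()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ValueError(f"{path}: no model element found")
    mets = [Metabolite(id=s.getId(), name=s.getName() or "",
                       compartment=s.getCompartment() or "")
            for s in sbml_model.getListOfSpecies()]
    reactions = []
    for rx in sbml_model.getListOfReactions():
        stoich: dict[str, float] = {}
        for ref in rx.getListOfReactants():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - (ref.getStoichiometry() or 1.0)
        for ref in rx.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + (ref.getStoichiometry() or 1.0)
        stoich = {k: v for k, v in stoich.items() if v != 0}
        genes: list[str] = []
        fbc = rx.getPlugin("fbc")
        if fbc is not None and fbc.getGeneProductAssociation() is not None:
            assoc = fbc.getGeneProductAssociation().getAssociation()
            genes = sorted(set(_collect_gene_refs(assoc)))
        reactions.append(Reaction(id=rx.getId(), stoichiometry=stoich,
                                  reversible=bool(rx.getReversible()),
                                  gene_association=genes, source=ReactionSource.BIGG,
                                  name=rx.getName() or ""))
    return MetabolicModel(metabolites=mets, reactions=reactions,
                          id=sbml_model.getId() or path.stem)


def _collect_gene_refs(assoc) -> list[str]:
    import libsbml

    if assoc is None:
        return []
    if isinstance(assoc, libsbml.GeneProductRef):
        return [assoc.getGeneProduct()]
    out: list[str] = []
    for i in range(assoc.getNumAssociations()):
        out.extend(_collect_gene_refs(assoc.getAssociation(i)))
    return out


_GENE_RULE_SPLIT = re.compile(r"\band\b|\bor\b|[()]", flags=re.IGNORECASE)


def parse_gene_rule(rule: str) -> list[str]:
    """Tokenize a BIGG gene_reaction_rule to bare gene ids (OR semantics)."""
    return sorted({tok.strip() for tok in _GENE_RULE_SPLIT.split(rule or "") if tok.strip()})


def _read_bigg_json(path: Path) -> MetabolicModel:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"BIGG JSON parse error in {path}: {exc}") from exc
    mets = [Metabolite(id=m["id"], name=m.get("name", ""),
                       compartment=m.get("compartment", ""))
            for m in payload.get("metabolites", [])]
    reactions = []
    for r in payload.get("reactions", []):
        stoich = {k: float(v) for k, v in r["metabolites"].items() if float(v) != 0}
        reactions.append(Reaction(
            id=r["id"], stoichiometry=stoich,
            reversible=float(r.get("lower_bound", 0)) < 0,
            gene_association=parse_gene_rule(r.get("gene_reaction_rule", "")),
            source=ReactionSource.BIGG, name=r.get("name", "")))
    return MetabolicModel(metabolites=mets, reactions=reactions,
                          id=payload.get("id", path.stem))


def write_genome_scale_model(model: MetabolicModel, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "bigg_json" if path.suffix == ".json" else "sbml"
    if format == "bigg_json":
        payload = {
            "id": model.id,
            "metabolites": [{"id": m.id, "name": m.name, "compartment": m.compartment}
                            for m in model.metabolites],
            "reactions": [{
                "id": r.id, "name": r.name, "metabolites": r.stoichiometry,
                "lower_bound": -1000.0 if r.reversible else 0.0, "upper_bound": 1000.0,
                "gene_reaction_rule": " or ".join(r.gene_association),
            } for r in model.reactions],
        }
        path.write_text(json.dumps(payload, indent=1))
        return
    if format == "sbml":
        _write_sbml(model, path)
        return
    raise ValueError(f"unknown model format {format!r}")


def _write_sbml(model: MetabolicModel, path: Path) -> None:
    import libsbml

    doc = libsbml.SBMLDocument(3, 2)
    sm = doc.createModel()
    sm.setId(model.id)
    compartments = {m.compartment or "c" for m in model.metabolites}
    for cid in sorted(compartments):
        comp = sm.createCompartment()
        comp.setId(cid)
        comp.setConstant(True)
    for m in model.metabolites:
        sp = sm.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment(m.compartment or "c")
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(False)
    for r in model.reactions:
        rx = sm.createReaction()
        rx.setId(r.id)
        rx.setName(r.name)
        rx.setReversible(r.reversible)
        for mid, coeff in r.stoichiometry.items():
            ref = rx.createReactant() if coeff < 0 else rx.createProduct()
            ref.setSpecies(mid)
            ref.setStoichiometry(abs(coeff))
            ref.setConstant(True)
    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise OSError(f"could not write SBML to {path}")


# ---------------------------------------------------------------------------
# KEGG

_KEGG_COEFF = re.compile(r"^(\d+)\s+(C\d{5})$")
_KEGG_PLAIN = re.compile(r"^(C\d{5})(\(\w+\))?$")


def parse_kegg_equation(equation: str) -> dict[str, float]:
    """Parse a KEGG EQUATION line into signed stoichiometry.

    Integer coefficients default to 1; substrate side of ``<=>`` is
    negative.  Raises ValueError on terms it cannot interpret (symbolic
    coefficients like ``n`` or glycan ids).
    """
    if "<=>" not in equation:
        raise ValueError("no '<=>' separator")
    left, right = equation.split("<=>")
    stoich: dict[str, float] = {}
    for side, sign in ((left, -1.0), (right, 1.0)):
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = _KEGG_COEFF.match(term)
            if m:
                cid, coeff = m.group(2), float(m.group(1))
            else:
                m = _KEGG_PLAIN.match(term)
                if not m:
                    raise ValueError(f"unparseable term {term!r}")
                cid, coeff = m.group(1), 1.0
            stoich[cid] = stoich.get(cid, 0.0) + sign * coeff
    stoich = {k: v for k, v in stoich.items() if v != 0}
    return stoich


def _parse_kegg_records(text: str):
    """Yield dicts of {ENTRY, EQUATION, ENZYME, NAME} from flat-file text."""
    for block in text.split("///"):
        if not block.strip():
            continue
        fields: dict[str, str] = {}
        key = None
        for line in block.splitlines():
            if not line.strip():
                continue
            head = line[:12].strip()
            if head:
                key = head
                fields[key] = line[12:].strip()
            elif key:
                fields[key] += " " + line[12:].strip()
        if fields:
            yield fields


def read_kegg_model(organism: str, source: str | Path | None = None,
                    live: bool = False, cache_dir: str | Path | None = None) -> MetabolicModel:
    """Build an organism-specific reaction model from KEGG flat files.

    ``source`` is a directory holding ``reactions.txt`` (concatenated
    KEGG reaction records) and ``<organism>_enzymes.tsv`` (two columns:
    gene id, EC number).  The model keeps exactly the reactions whose
    ENZYME entries intersect the organism's enzyme list.  Live retrieval
    from the KEGG REST API is opt-in and caches into ``cache_dir``.
    """
    if source is None and not live:
        raise FileNotFoundError(
            "offline KEGG access requires a cache directory; pass source=... or live=True")
    if source is None:
        source = _kegg_fetch(organism, Path(cache_dir or ".kegg_cache"))
    source = Path(source)
    reactions_file = source / "reactions.txt"
    enzyme_file = source / f"{organism}_enzymes.tsv"
    for f in (reactions_file, enzyme_file):
        if not f.exists():
            raise FileNotFoundError(f"missing KEGG cache file {f}")

    enzyme_genes: dict[str, list[str]] = {}
    for line in enzyme_file.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        gene, ec = line.split("\t")[:2]
        ec = ec.split(":")[-1].strip()
        enzyme_genes.setdefault(ec, []).append(gene.split(":")[-1].strip())
    organism_enzymes = set(enzyme_genes)

    reactions: list[Reaction] = []
    compounds: dict[str, Metabolite] = {}
    skipped = 0
    for rec in _parse_kegg_records(reactions_file.read_text()):
        entry = rec.get("ENTRY", "").split()[0] if rec.get("ENTRY") else ""
        ecs = set(rec.get("ENZYME", "").split())
        hit = ecs & organism_enzymes
        if not hit:
            continue
        try:
            stoich = parse_kegg_equation(rec.get("EQUATION", ""))
            genes = sorted({g for ec in hit for g in enzyme_genes[ec]})
            rx = Reaction(id=entry or f"R_{len(reactions)}", stoichiometry=stoich,
                          reversible=True, gene_association=genes,
                          source=ReactionSource.KEGG,
                          name=rec.get("NAME", ""))
        except ValueError as exc:
            skipped += 1
            log.warning("skipping KEGG record %s: %s", entry, exc)
            continue
        reactions.append(rx)
        for cid in stoich:
            compounds.setdefault(cid, Metabolite(id=cid, xrefs={"kegg.compound": cid}))
    if skipped:
        log.warning("skipped %d malformed KEGG reaction records", skipped)
    return MetabolicModel(metabolites=list(compounds.values()), reactions=reactions,
                          organism=organism, id=f"kegg_{organism}")


def _kegg_fetch(organism: str, cache_dir: Path) -> Path:
    """Minimal KEGG REST retrieval (explicitly opted in; cached)."""
    import urllib.request

    cache_dir.mkdir(parents=True, exist_ok=True)
    enzyme_file = cache_dir / f"{organism}_enzymes.tsv"
    if not enzyme_file.exists():
        with urllib.request.urlopen(f"https://rest.kegg.jp/link/enzyme/{organism}") as resp:
            enzyme_file.write_bytes(resp.read())
    reactions_file = cache_dir / "reactions.txt"
    if not reactions_file.exists():
        raise FileNotFoundError(
            f"place concatenated KEGG reaction records at {reactions_file}; "
            "bulk reaction download is not automated")
    return cache_dir


# ---------------------------------------------------------------------------
# ModelSEED thermodynamics

def read_modelseed_thermo(path, id_column: str = "id", dg_column: str = "deltag",
                          direction_column: str = "direction") -> dict[str, ReactionThermo]:
    """Load the ModelSEED reactions TSV into per-reaction thermodynamics.

    The ModelSEED missing-value sentinel 10000000 maps to "no estimate".
    """
    import pandas as pd

    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    missing = [c for c in (id_column, dg_column) if c not in df.columns]
    if missing:
        raise ValueError(
            f"ModelSEED table lacks required columns {missing}; found {list(df.columns)}")
    direction_map = {">": "forward", "<": "reverse", "=": "reversible"}
    out: dict[str, ReactionThermo] = {}
    for _, row in df.iterrows():
        rid = row[id_column]
        dg: float | None
        try:
            dg = float(row[dg_column])
        except (TypeError, ValueError):
            dg = None
        if dg is not None and (abs(dg) >= MODELSEED_MISSING_DG or not np_isfinite(dg)):
            dg = None
        hint = "unknown"
        if direction_column in df.columns and dg is not None:
            hint = direction_map.get(str(row[direction_column]).strip(), "unknown")
        out[rid] = ReactionThermo(reaction_id=rid, delta_g=dg, direction_hint=hint)
    return out


def np_isfinite(x: float) -> bool:
    import math

    return math.isfinite(x)


# ---------------------------------------------------------------------------
# trimming and mapping

def trim_by_expression(model: MetabolicModel, expression: dict[str, float],
                       threshold: float) -> MetabolicModel:
    """Discard reactions whose every associated gene is expressed below threshold.

    Reactions without gene associations, and genes missing from the
    expression table, never cause removal (OR semantics over genes).
    """
    import math

    if not math.isfinite(threshold) and threshold > 0:
        raise ValueError("threshold must be finite or -inf")
    kept = []
    for r in model.reactions:
        if not r.gene_association:
            kept.append(r)
            continue
        values = [expression[g] for g in r.gene_association if g in expression]
        missing = [g for g in r.gene_association if g not in expression]
        if missing:
            log.info("reaction %s: no expression data for %s", r.id, missing)
        if values and all(v < threshold for v in values) and not missing:
            continue
        kept.append(r)
    used = {m for r in kept for m in r.stoichiometry}
    mets = [m for m in model.metabolites if m.id in used] or model.metabolites
    return MetabolicModel(metabolites=list(mets), reactions=list(kept),
                          organism=model.organism, id=model.id)


def map_metabolites(names: list[str], mapping: MetaboliteMapping | None,
                    model: MetabolicModel) -> list[str]:
    """Resolve dataset metabolite names to model ids, preserving input order.

    The output order defines the Jacobian row/column order downstream.
    All unmapped names are reported together in one error.
    """
    known = set(model.metabolite_ids)
    resolved: list[str] = []
    misses: list[str] = []
    for name in names:
        if name in known:
            resolved.append(name)
            continue
        candidates = mapping.table.get(name, []) if mapping else []
        candidates = [c for c in candidates if c in known]
        if not candidates:
            misses.append(name)
            continue
        if len(candidates) > 1:
            log.warning("ambiguous mapping for %r: %s (using first)", name, candidates)
        resolved.append(candidates[0])
    if misses:
        raise MappingError(misses)
    return resolved
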