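"""The 60-variable validation-set encoding.

Every activity record ("experimental fact") becomes one row of exactly
60 features drawn from six families: chemical descriptors of the
compound, assay metadata, target metadata, taxonomy, cell line/tissue,
and enumerated bookkeeping variables — plus a categorical activity
label and the compound's averaged melatonin potency score.

Categorical variables are dictionary/integer encoded (random forests
split on them directly); dictionaries are fitted once, sorted for
determinism, and persisted with the model.  The missing-value sentinel
is -1 for categoricals and the fitted median for numerics.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, Lipinski, QED, rdMolDescriptors

from .activity_io import ActivityRecord, LinkedTable
from .potency_scoring import SubtypeAverage

RDLogger.DisableLog("rdApp.*")

N_FEATURES = 60

CHEMICAL_DESCRIPTORS = (
    "molecular_weight", "qed_weighted", "logp", "tpsa", "hbd", "hba",
    "rotatable_bonds", "aromatic_rings", "heavy_atoms", "ring_count",
    "fraction_csp3", "molar_refractivity", "n_heteroatoms",
    "n_saturated_rings", "n_aliphatic_rings", "formal_charge",
    "n_nitrogen", "n_oxygen", "n_sulfur", "n_halogen",
)

_ASSAY_KEYWORDS = (
    "binding", "functional", "inhibition", "agonist", "antagonist",
    "radioligand", "cell", "membrane", "receptor", "affinity", "in vivo",
)

_MAMMALS = frozenset({
    "homo sapiens", "rattus norvegicus", "mus musculus",
    "oryctolagus cuniculus", "cavia porcellus", "canis familiaris",
    "sus scrofa", "bos taurus", "ovis aries", "mesocricetus auratus",
})

_CARDIAC_TISSUE_TERMS = ("heart", "cardiac", "aorta", "atri", "ventric",
                         "coronary", "vascular")


@dataclass(frozen=True)
class FeatureVariable:
    name: str
    family: str   # chemical | assay | target | taxonomy | cell_line_tissue | enumerated
    kind: str     # numeric | categorical


@dataclass
class FeatureConfig:
    """Knobs for schema construction and target/taxonomy flags."""

    subtype_ids: tuple[str, ...] = ("MTNR1A", "MTNR1B", "MTNR1C")
    gpcr_class: str = "GPCR"
    label_threshold: float = 4.0
    inactive_placeholder: float = 0.0


def compute_descriptors(smiles: str) -> dict[str, float]:
    """Chemical descriptors for one structure.

    Raises ``ValueError`` for an unparseable SMILES.  Molecular weight
    uses average atomic masses (g/mol); QED is the Bickerton weighted
    quantitative estimate of drug-likeness.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    halogens = sum(1 for a in mol.GetAtoms()
                   if a.GetSymbol() in ("F", "Cl", "Br", "I"))
    count = lambda sym: sum(1 for a in mol.GetAtoms() if a.GetSymbol() == sym)
    return {
        "molecular_weight": Descriptors.MolWt(mol),
        "qed_weighted": QED.qed(mol),
        "logp": Crippen.MolLogP(mol),
        "tpsa": rdMolDescriptors.CalcTPSA(mol),
        "hbd": Lipinski.NumHDonors(mol),
        "hba": Lipinski.NumHAcceptors(mol),
        "rotatable_bonds": Lipinski.NumRotatableBonds(mol),
        "aromatic_rings": rdMolDescriptors.CalcNumAromaticRings(mol),
        "heavy_atoms": mol.GetNumHeavyAtoms(),
        "ring_count": rdMolDescriptors.CalcNumRings(mol),
        "fraction_csp3": rdMolDescriptors.CalcFractionCSP3(mol),
        "molar_refractivity": Crippen.MolMR(mol),
        "n_heteroatoms": rdMolDescriptors.CalcNumHeteroatoms(mol),
        "n_saturated_rings": rdMolDescriptors.CalcNumSaturatedRings(mol),
        "n_aliphatic_rings": rdMolDescriptors.CalcNumAliphaticRings(mol),
        "formal_charge": Chem.GetFormalCharge(mol),
        "n_nitrogen": count("N"),
        "n_oxygen": count("O"),
        "n_sulfur": count("S"),
        "n_halogen": halogens,
    }


@dataclass
class FeatureSchema:
    """Ordered definition of the 60 validation-set variables."""

    variables: list[FeatureVariable]

    def __post_init__(self) -> None:
        if len(self.variables) != N_FEATURES:
            raise ValueError(
                f"schema must have exactly {N_FEATURES} variables, "
                f"got {len(self.variables)}")
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise ValueError("duplicate variable names in schema")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def fingerprint(self) -> str:
        payload = json.dumps(
            [(v.name, v.family, v.kind) for v in self.variables])
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def family_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for v in self.variables:
            out[v.family] = out.get(v.family, 0) + 1
        return out

    def to_json(self) -> str:
        return json.dumps(
            [{"name": v.name, "family": v.family, "kind": v.kind}
             for v in self.variables], indent=1)


def build_schema(config: Optional[FeatureConfig] = None) -> FeatureSchema:
    """Construct the default 60-variable schema.

    Composition: 20 chemical, 14 assay, 10 target, 6 taxonomy,
    6 cell-line/tissue, 4 enumerated.
    """
    variables: list[FeatureVariable] = []
    var = lambda n, f, k: variables.append(FeatureVariable(n, f, k))

    for name in CHEMICAL_DESCRIPTORS:                      # 20 chemical
        var(name, "chemical", "numeric")

    var("assay_type_code", "assay", "categorical")         # 14 assay
    var("bao_format_code", "assay", "categorical")
    var("n_molecules_seen", "assay", "numeric")
    for kw in _ASSAY_KEYWORDS:
        var("kw_" + kw.replace(" ", "_"), "assay", "numeric")

    var("target_code", "target", "categorical")            # 10 target
    var("target_class_code", "target", "categorical")
    for flag in ("is_gpcr", "is_mtnr1a", "is_mtnr1b", "is_mtnr1c",
                 "is_melatonin_receptor", "is_kinase", "is_ion_channel",
                 "is_enzyme"):
        var("target_" + flag, "target", "numeric")

    var("organism_code", "taxonomy", "categorical")        # 6 taxonomy
    for flag in ("is_human", "is_rat", "is_mouse", "is_mammal",
                 "is_other_organism"):
        var("taxon_" + flag, "taxonomy", "numeric")

    var("cell_line_code", "cell_line_tissue", "categorical")  # 6 cell/tissue
    var("tissue_code", "cell_line_tissue", "categorical")
    for flag in ("has_cell_line", "has_tissue", "tissue_is_cardiac",
                 "cell_is_recombinant_host"):
        var(flag, "cell_line_tissue", "numeric")

    var("standard_type_code", "enumerated", "categorical")  # 4 enumerated
    var("standard_relation_code", "enumerated", "categorical")
    var("standard_units_code", "enumerated", "categorical")
    var("assay_code", "enumerated", "categorical")

    return FeatureSchema(variables)


class FeatureEncoder:
    """Fits category dictionaries / medians, then encodes records to rows.

    ``fit`` scans a linked table; ``encode`` turns any subset of its
    records into the validation-row DataFrame.  Encoding is a pure
    function of (schema, fitted dictionaries), so the same encoder
    applied twice yields identical output.
    """

    def __init__(self, schema: FeatureSchema,
                 config: Optional[FeatureConfig] = None) -> None:
        self.schema = schema
        self.config = config or FeatureConfig()
        self.dictionaries: dict[str, dict[str, int]] = {}
        self.medians: dict[str, float] = {}
        self._descriptor_cache: dict[str, Optional[dict[str, float]]] = {}
        self._fitted = False

    # -- fitting -------------------------------------------------------
    def fit(self, linked: LinkedTable) -> "FeatureEncoder":
        cats: dict[str, set[str]] = {
            v.name: set() for v in self.schema.variables
            if v.kind == "categorical"}
        for rec, comp, assay in linked.iter_resolved():
            raw = self._raw_categoricals(rec, assay)
            for name, value in raw.items():
                if name in cats:
                    cats[name].add(value)
        self.dictionaries = {
            name: {v: i for i, v in enumerate(sorted(values))}
            for name, values in cats.items()}
        # chemical medians for sentinel imputation of structureless compounds
        desc_rows = []
        for comp in linked.compounds.values():
            d = self._descriptors_for(comp.compound_id, comp.smiles)
            if d is not None:
                desc_rows.append(d)
        if desc_rows:
            frame = pd.DataFrame(desc_rows)
            self.medians = {c: float(frame[c].median()) for c in frame}
        else:
            self.medians = {name: 0.0 for name in CHEMICAL_DESCRIPTORS}
        self._fitted = True
        return self

    def _descriptors_for(self, compound_id: str,
                         smiles: Optional[str]) -> Optional[dict[str, float]]:
        if compound_id in self._descriptor_cache:
            return self._descriptor_cache[compound_id]
        result: Optional[dict[str, float]] = None
        if smiles:
            try:
                result = compute_descriptors(smiles)
            except ValueError:
                warnings.warn(
                    f"compound {compound_id}: unparseable structure; "
                    "chemical features imputed", stacklevel=2)
        else:
            warnings.warn(
                f"compound {compound_id}: no structure; chemical "
                "features imputed", stacklevel=2)
        self._descriptor_cache[compound_id] = result
        return result

    @staticmethod
    def _raw_categoricals(rec: ActivityRecord, assay) -> dict[str, str]:
        return {
            "assay_type_code": assay.assay_type or "",
            "bao_format_code": assay.bao_format or "",
            "target_code": rec.target_id or "",
            "target_class_code": assay.target_class or "",
            "organism_code": assay.organism or "",
            "cell_line_code": assay.cell_line or "",
            "tissue_code": assay.tissue or "",
            "standard_type_code": rec.standard_type,
            "standard_relation_code": rec.standard_relation,
            "standard_units_code": rec.standard_units or "",
            "assay_code": rec.assay_id,
        }

    # -- encoding ------------------------------------------------------
    def _encode_one(self, rec: ActivityRecord, comp, assay) -> dict[str, float]:
        cfg = self.config
        row: dict[str, float] = {}
        desc = self._descriptors_for(comp.compound_id, comp.smiles)
        for name in CHEMICAL_DESCRIPTORS:
            row[name] = (desc[name] if desc is not None
                         else self.medians.get(name, 0.0))
        raw = self._raw_categoricals(rec, assay)
        for name, value in raw.items():
            row[name] = float(self.dictionaries.get(name, {}).get(value, -1))
        row["n_molecules_seen"] = float(assay.n_molecules_seen)
        desc_lower = (assay.description or "").lower()
        for kw in _ASSAY_KEYWORDS:
            row["kw_" + kw.replace(" ", "_")] = float(kw in desc_lower)
        tid = rec.target_id or ""
        tclass = (assay.target_class or "").lower()
        row["target_is_gpcr"] = float(cfg.gpcr_class.lower() in tclass)
        for i, flag in enumerate(("is_mtnr1a", "is_mtnr1b", "is_mtnr1c")):
            row["target_" + flag] = float(
                i < len(cfg.subtype_ids) and tid == cfg.subtype_ids[i])
        row["target_is_melatonin_receptor"] = float(tid in cfg.subtype_ids)
        row["target_is_kinase"] = float("kinase" in tclass)
        row["target_is_ion_channel"] = float("ion channel" in tclass)
        row["target_is_enzyme"] = float("enzyme" in tclass)
        org = (assay.organism or "").lower()
        row["taxon_is_human"] = float(org == "homo sapiens")
        row["taxon_is_rat"] = float(org == "rattus norvegicus")
        row["taxon_is_mouse"] = float(org == "mus musculus")
        row["taxon_is_mammal"] = float(org in _MAMMALS)
        row["taxon_is_other_organism"] = float(
            bool(org) and org not in _MAMMALS)
        row["has_cell_line"] = float(bool(assay.cell_line))
        row["has_tissue"] = float(bool(assay.tissue))
        tissue = (assay.tissue or "").lower()
        row["tissue_is_cardiac"] = float(
            any(t in tissue for t in _CARDIAC_TISSUE_TERMS))
        cell = (assay.cell_line or "").upper()
        row["cell_is_recombinant_host"] = float(
            any(h in cell for h in ("CHO", "HEK", "COS")))
        return row

    def encode(self, records: Iterable[ActivityRecord],
               linked: LinkedTable,
               averages: Mapping[str, SubtypeAverage],
               label_threshold: Optional[float] = None) -> pd.DataFrame:
        """Encode records into validation rows.

        Output columns: ``record_id``, ``compound_id``, the 60 schema
        features in order, ``label`` and ``activity_score``.  A record
        is labeled active iff its compound's averaged melatonin
        potency score strictly exceeds the threshold; compounds with
        no measured melatonin score receive the inactive placeholder.
        """
        if not self._fitted:
            raise RuntimeError("encoder must be fitted before encoding")
        thr = (self.config.label_threshold if label_threshold is None
               else label_threshold)
        rows = []
        for rec in records:
            comp = linked.compounds[rec.compound_id]
            assay = linked.assays[rec.assay_id]
            row = self._encode_one(rec, comp, assay)
            avg = averages.get(rec.compound_id)
            score = (avg.average_score if avg is not None
                     else self.config.inactive_placeholder)
            row_out = {"record_id": rec.record_id,
                       "compound_id": rec.compound_id}
            row_out.update({name: row[name] for name in self.schema.names})
            row_out["label"] = "active" if score > thr else "inactive"
            row_out["activity_score"] = score
            rows.append(row_out)
        cols = (["record_id", "compound_id"] + self.schema.names
                + ["label", "activity_score"])
        return pd.DataFrame(rows, columns=cols)

    def feature_matrix(self, rows: pd.DataFrame) -> np.ndarray:
        return rows[self.schema.names].to_numpy(dtype=float)
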