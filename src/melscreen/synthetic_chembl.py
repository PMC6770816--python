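"""Synthetic miniature ChEMBL universe with known ground truth.

Emulates the statistical structure of a ChEMBL bioactivity export for
melatonin-receptor pharmacology:

* compounds with latent log-potency per melatonin receptor subtype,
  drawn from a multivariate normal with configurable between-subtype
  correlation (active mean 7, inactive mean 2, on the -log10 molar
  scale);
* measurements = latent + noise, emitted in a heterogeneous mixture of
  standard types and units (nM / uM / ug/mL, plus a few percent-
  inhibition readouts), with a configurable right-censored fraction;
* a GPCR inactivity panel planting "Not Active" evidence for negative
  augmentation;
* cardiovascular assays in which a configured subset of the true
  actives is also potent (score > 5).

Generation is a pure function of the config (seed included): the same
config yields byte-identical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Descriptors

from ._structures import DRUG_STRUCTURES
from .activity_io import ActivityRecord, AssayProfile, CompoundProfile

RDLogger.DisableLog("rdApp.*")

SUBTYPE_IDS = ("MTNR1A", "MTNR1B", "MTNR1C")

_ORGANISMS = ("Homo sapiens", "Rattus norvegicus", "Mus musculus",
              "Cavia porcellus")
_CONC_TYPES = ("IC50", "EC50", "Ki", "Kd")
_CELL_LINES = ("CHO", "HEK293", "COS-7")

_CV_TEMPLATES_VIVO = (
    "In vivo effect on blood pressure in {org}",
    "Antiarrhythmic activity in {org} model of induced arrhythmia",
    "In vivo reduction of cardiac infarct size in {org}",
    "Antihypertensive effect in spontaneously hypertensive {org}",
)
_CV_TEMPLATES_VITRO = (
    "Inhibition of aortic ring contraction",
    "Vasodilator activity in isolated coronary artery",
    "Negative inotropic effect in isolated atrial preparation",
    "Block of ventricular potassium current in transfected cells",
)
_CV_TISSUES = ("heart", "aorta", "coronary artery", "left ventricle")


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic universe."""

    seed: int
    n_compounds: int = 2000
    fraction_melatonin_active: float = 0.30
    subtype_correlation: float = 0.9
    n_melatonin_assays_per_subtype: int = 10
    n_gpcr_panel_assays: int = 50
    n_cv_assays: int = 40
    fraction_active_also_cv_potent: float = 0.25
    noise_sd: float = 0.5
    #: unit mixture for concentration measurements (must sum to 1)
    unit_mixture: dict = field(default_factory=lambda: {
        "nM": 0.55, "uM": 0.30, "ug/mL": 0.15})
    censored_fraction: float = 0.05
    percent_fraction: float = 0.03
    #: fraction of inactive compounds that are weakly measured at the
    #: melatonin receptors (the rest populate the GPCR panel)
    fraction_inactive_measured: float = 0.30
    #: fraction of panel compounds planted with >= 10 inactive GPCR assays
    gpcr_eligible_fraction: float = 0.60
    #: fraction of compounds carrying a drug name
    named_fraction: float = 0.15
    #: activity records pointing at an unknown compound id (plumbing tests)
    n_orphans: int = 0
    active_latent_mean: float = 7.0
    inactive_latent_mean: float = 2.0
    latent_sd: float = 1.0
    activity_threshold: float = 4.0

    def validate(self) -> None:
        fracs = (self.fraction_melatonin_active,
                 self.fraction_active_also_cv_potent,
                 self.censored_fraction, self.percent_fraction,
                 self.fraction_inactive_measured,
                 self.gpcr_eligible_fraction, self.named_fraction)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must be in [0, 1]")
        if not -1.0 <= self.subtype_correlation <= 1.0:
            raise ValueError("subtype correlation must be in [-1, 1]")
        if min(self.n_compounds, self.n_melatonin_assays_per_subtype,
               self.n_gpcr_panel_assays, self.n_cv_assays) < 0:
            raise ValueError("counts must be non-negative")
        total = sum(self.unit_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("unit mixture proportions must sum to 1")


@dataclass
class GroundTruth:
    """What the generator planted, keyed by compound/assay id."""

    latent_by_subtype: dict[str, dict[str, float]]
    latent_mean: dict[str, float]
    true_active: dict[str, bool]
    is_cv_potent: dict[str, bool]
    gpcr_eligible: dict[str, bool]
    assay_category: dict[str, str]
    activity_threshold: float


@dataclass
class SyntheticUniverse:
    records: list[ActivityRecord]
    compounds: list[CompoundProfile]
    assays: list[AssayProfile]
    truth: GroundTruth
    config: SyntheticConfig


def _mol_weights() -> dict[str, float]:
    out = {}
    for name, smi in DRUG_STRUCTURES:
        out[smi] = Descriptors.MolWt(Chem.MolFromSmiles(smi))
    return out


_MW_BY_SMILES = _mol_weights()


def _draw_latents(rng: np.random.Generator, n: int, mean: float, sd: float,
                  rho: float, above: Optional[float], below: Optional[float],
                  ) -> np.ndarray:
    """Correlated subtype latents, redrawn until the mean respects the
    activity threshold so planted labels are exact."""
    k = len(SUBTYPE_IDS)
    cov = sd ** 2 * (np.full((k, k), rho) + (1 - rho) * np.eye(k))
    out = np.empty((n, k))
    for i in range(n):
        for _ in range(1000):
            draw = rng.multivariate_normal(np.full(k, mean), cov,
                                           method="cholesky")
            m = draw.mean()
            if (above is None or m > above) and (below is None or m < below):
                out[i] = draw
                break
        else:
            raise RuntimeError("latent rejection sampling did not converge")
    return out


def generate(config: SyntheticConfig) -> SyntheticUniverse:
    """Build the full synthetic universe (records, compounds, assays)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    # -- compounds ----------------------------------------------------
    n = config.n_compounds
    structures = [DRUG_STRUCTURES[i % len(DRUG_STRUCTURES)]
                  for i in range(n)]
    if config.unit_mixture.get("ug/mL", 0) > 0 and any(
            not smi for _, smi in structures):
        raise ValueError("ug/mL records require structures with weights")
    named = rng.random(n) < config.named_fraction
    compounds = []
    for i, (name, smi) in enumerate(structures):
        compounds.append(CompoundProfile(
            compound_id=f"C{i:05d}",
            smiles=smi,
            pref_name=name if named[i] else None,
            max_phase=int(rng.integers(0, 5)) if named[i] else 0,
        ))

    n_active = round(n * config.fraction_melatonin_active)
    order = rng.permutation(n)
    active_idx = set(order[:n_active].tolist())
    thr = config.activity_threshold
    margin = 0.2  # keep planted labels away from the exact boundary
    lat_active = _draw_latents(rng, n_active, config.active_latent_mean,
                               config.latent_sd, config.subtype_correlation,
                               above=thr + margin, below=None)
    lat_inactive = _draw_latents(rng, n - n_active,
                                 config.inactive_latent_mean,
                                 config.latent_sd,
                                 config.subtype_correlation,
                                 above=None, below=thr - margin)
    latent_by_subtype: dict[str, dict[str, float]] = {}
    latent_mean: dict[str, float] = {}
    true_active: dict[str, bool] = {}
    ia = ii = 0
    for i, comp in enumerate(compounds):
        if i in active_idx:
            row, ia = lat_active[ia], ia + 1
            true_active[comp.compound_id] = True
        else:
            row, ii = lat_inactive[ii], ii + 1
            true_active[comp.compound_id] = False
        latent_by_subtype[comp.compound_id] = dict(zip(SUBTYPE_IDS, row))
        latent_mean[comp.compound_id] = float(row.mean())

    # -- assays -------------------------------------------------------
    assays: list[AssayProfile] = []
    assay_category: dict[str, str] = {}
    mel_assays_by_subtype: dict[str, list[str]] = {}
    for subtype in SUBTYPE_IDS:
        mel_assays_by_subtype[subtype] = []
        for j in range(config.n_melatonin_assays_per_subtype):
            aid = f"A_MEL_{subtype}_{j:02d}"
            org = _ORGANISMS[int(rng.integers(0, len(_ORGANISMS)))]
            kind = "binding" if rng.random() < 0.6 else "functional"
            assays.append(AssayProfile(
                assay_id=aid,
                description=(f"{kind.capitalize()} assay of affinity at "
                             f"{subtype} melatonin receptor"),
                assay_type=kind,
                target_class="GPCR",
                organism=org,
                cell_line=_CELL_LINES[int(rng.integers(0, 3))]
                if rng.random() < 0.7 else None,
                bao_format="BAO_0000219",
            ))
            assay_category[aid] = f"melatonin:{subtype}"
            mel_assays_by_subtype[subtype].append(aid)
    gpcr_assays = []
    for j in range(config.n_gpcr_panel_assays):
        aid = f"A_GPCR_{j:03d}"
        assays.append(AssayProfile(
            assay_id=aid,
            description=f"Binding affinity at GPCR panel member {j}",
            assay_type="binding",
            target_class="GPCR",
            organism=_ORGANISMS[int(rng.integers(0, len(_ORGANISMS)))],
            cell_line=_CELL_LINES[int(rng.integers(0, 3))],
            bao_format="BAO_0000219",
        ))
        assay_category[aid] = "gpcr_panel"
        gpcr_assays.append(aid)
    cv_assays = []
    for j in range(config.n_cv_assays):
        aid = f"A_CV_{j:03d}"
        org = _ORGANISMS[int(rng.integers(0, len(_ORGANISMS)))]
        in_vivo = rng.random() < 0.5
        if in_vivo:
            desc = _CV_TEMPLATES_VIVO[
                int(rng.integers(0, len(_CV_TEMPLATES_VIVO)))].format(org=org)
            tissue = _CV_TISSUES[int(rng.integers(0, len(_CV_TISSUES)))]
            cell = None
        else:
            desc = _CV_TEMPLATES_VITRO[
                int(rng.integers(0, len(_CV_TEMPLATES_VITRO)))]
            tissue = None
            cell = _CELL_LINES[int(rng.integers(0, 3))]
        assays.append(AssayProfile(
            assay_id=aid, description=desc, assay_type="functional",
            target_class="other", organism=org, cell_line=cell,
            tissue=tissue, bao_format="BAO_0000218"))
        assay_category[aid] = "cv"
        cv_assays.append(aid)

    # -- activity records --------------------------------------------
    records: list[ActivityRecord] = []
    seq = iter(range(10 ** 7))

    def emit_conc(cid: str, aid: str, tid: Optional[str], score: float,
                  smiles: str) -> None:
        """One concentration record at the given -log10 molar score."""
        rid = f"R{next(seq):07d}"
        stype = _CONC_TYPES[int(rng.integers(0, len(_CONC_TYPES)))]
        units = rng.choice(list(config.unit_mixture),
                           p=list(config.unit_mixture.values()))
        molar = 10.0 ** (-score)
        if units == "nM":
            value = molar / 1e-9
        elif units == "uM":
            value = molar / 1e-6
        else:  # ug/mL
            value = molar * _MW_BY_SMILES[smiles] * 1e3
        relation = ">" if rng.random() < config.censored_fraction else "="
        records.append(ActivityRecord(
            record_id=rid, compound_id=cid, assay_id=aid, target_id=tid,
            standard_type=stype, standard_relation=relation,
            standard_value=float(value), standard_units=str(units)))

    def emit_percent(cid: str, aid: str, tid: Optional[str]) -> None:
        records.append(ActivityRecord(
            record_id=f"R{next(seq):07d}", compound_id=cid, assay_id=aid,
            target_id=tid, standard_type="Inhibition",
            standard_relation="=",
            standard_value=float(np.round(rng.uniform(10, 95), 1)),
            standard_units="%"))

    def emit_not_active(cid: str, aid: str, tid: Optional[str]) -> None:
        records.append(ActivityRecord(
            record_id=f"R{next(seq):07d}", compound_id=cid, assay_id=aid,
            target_id=tid, standard_type="IC50", standard_relation="=",
            standard_value=None, standard_units=None,
            activity_comment="Not Active"))

    all_mel_assays = [(a, s) for s in SUBTYPE_IDS
                      for a in mel_assays_by_subtype[s]]
    inactive_ids = [c.compound_id for i, c in enumerate(compounds)
                    if i not in active_idx]
    n_measured_weak = round(len(inactive_ids)
                            * config.fraction_inactive_measured)
    weak_ids = set(inactive_ids[:n_measured_weak])
    panel_ids = inactive_ids[n_measured_weak:]
    smiles_of = {c.compound_id: c.smiles for c in compounds}

    # melatonin measurements: actives richly, weak inactives sparsely
    for comp in compounds:
        cid = comp.compound_id
        if true_active[cid]:
            k = int(rng.integers(5, 13))
        elif cid in weak_ids:
            k = int(rng.integers(2, 7))
        else:
            continue
        pick = rng.choice(len(all_mel_assays), size=min(k,
                          len(all_mel_assays)), replace=False)
        for idx in sorted(pick):
            aid, subtype = all_mel_assays[idx]
            if rng.random() < config.percent_fraction:
                emit_percent(cid, aid, subtype)
                continue
            score = (latent_by_subtype[cid][subtype]
                     + rng.normal(0.0, config.noise_sd))
            emit_conc(cid, aid, subtype, score, smiles_of[cid])

    # GPCR panel inactivity evidence
    gpcr_eligible: dict[str, bool] = {c.compound_id: False
                                      for c in compounds}
    for cid in panel_ids:
        eligible = rng.random() < config.gpcr_eligible_fraction
        lo, hi = (10, min(21, len(gpcr_assays) + 1)) if eligible else (2, 9)
        m = int(rng.integers(lo, hi))
        m = min(m, len(gpcr_assays))
        gpcr_eligible[cid] = m >= 10
        pick = rng.choice(len(gpcr_assays), size=m, replace=False)
        for idx in sorted(pick):
            aid = gpcr_assays[idx]
            if rng.random() < 0.5:
                emit_not_active(cid, aid, f"GPCR_T{idx:03d}")
            else:
                weak_score = rng.uniform(1.0, 3.5)
                emit_conc(cid, aid, f"GPCR_T{idx:03d}", weak_score,
                          smiles_of[cid])

    # cardiovascular assays: potent subset of actives plus weak background
    active_ids = [compounds[i].compound_id for i in sorted(active_idx)]
    n_cv_potent = round(len(active_ids)
                        * config.fraction_active_also_cv_potent)
    cv_pick = rng.choice(len(active_ids), size=n_cv_potent, replace=False)
    is_cv_potent = {c.compound_id: False for c in compounds}
    if cv_assays:
        for idx in sorted(cv_pick):
            cid = active_ids[idx]
            is_cv_potent[cid] = True
            for _ in range(int(rng.integers(1, 4))):
                aid = cv_assays[int(rng.integers(0, len(cv_assays)))]
                score = rng.uniform(5.2, 7.0)
                emit_conc(cid, aid, None, score, smiles_of[cid])
        n_bg = round(0.15 * n)
        bg = rng.choice(n, size=n_bg, replace=False)
        for i in sorted(bg):
            cid = compounds[i].compound_id
            aid = cv_assays[int(rng.integers(0, len(cv_assays)))]
            emit_conc(cid, aid, None, rng.uniform(1.5, 4.2), smiles_of[cid])

    # planted orphans referencing unknown compounds
    for j in range(config.n_orphans):
        records.append(ActivityRecord(
            record_id=f"R{next(seq):07d}",
            compound_id=f"ORPHAN{j:03d}",
            assay_id=gpcr_assays[0] if gpcr_assays else "A_NONE",
            standard_type="IC50", standard_relation="=",
            standard_value=1000.0, standard_units="nM"))

    truth = GroundTruth(
        latent_by_subtype=latent_by_subtype,
        latent_mean=latent_mean,
        true_active=true_active,
        is_cv_potent=is_cv_potent,
        gpcr_eligible=gpcr_eligible,
        assay_category=assay_category,
        activity_threshold=thr,
    )
    return SyntheticUniverse(records=records, compounds=compounds,
                             assays=assays, truth=truth, config=config)


def truth_report(truth: GroundTruth,
                 screen_results: Sequence,
                 cv_hits: Sequence,
                 hit_threshold: float = 4.0) -> dict:
    """Recovery metrics of the pipeline against the planted truth."""
    from scipy import stats
    from sklearn.metrics import roc_auc_score

    by_id = {r.compound_id: r for r in screen_results}
    unknown = [cid for cid in by_id if cid not in truth.true_active]
    if unknown:
        raise ValueError(
            f"screen results contain {len(unknown)} compound ids absent "
            "from the ground truth")
    cids = sorted(by_id)
    y_true = np.array([truth.true_active[c] for c in cids])
    score = np.array([by_id[c].melatonin_score for c in cids])
    called = np.array([by_id[c].is_hit for c in cids])
    tp = int(np.sum(called & y_true))
    tn = int(np.sum(~called & ~y_true))
    fp = int(np.sum(called & ~y_true))
    fn = int(np.sum(~called & y_true))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    auroc = (float(roc_auc_score(y_true, score))
             if 0 < y_true.sum() < len(y_true) else float("nan"))
    latent = np.array([truth.latent_mean[c] for c in cids])
    rank_r = float(stats.spearmanr(score, latent).statistic)
    planted_cv = {c for c, f in truth.is_cv_potent.items() if f}
    recovered_cv = {h.compound_id for h in cv_hits} & planted_cv
    recovery = (len(recovered_cv) / len(planted_cv)
                if planted_cv else float("nan"))
    return {
        "n_compounds": len(cids),
        "sensitivity": sens,
        "specificity": spec,
        "auroc": auroc,
        "rank_correlation_vs_latent": rank_r,
        "cv_potent_planted": len(planted_cv),
        "cv_potent_recovered": len(recovered_cv),
        "cv_recovery_rate": recovery,
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }
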