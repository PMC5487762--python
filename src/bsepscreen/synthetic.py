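"""Synthetic datasets with the class-conditional structure the pipeline assumes.

The generator emulates a BSEP inhibition panel: 113 inhibitors and 295
non-inhibitors by default, Gaussian class-conditional docking scores per
scoring function (inhibitor ChemScore-like scores centered in the 35-40
band), MW/logP class distributions straddling the 390 Da / 3.6 cut-offs,
biased fingerprint bits, functional-group presence probabilities, and
residue-contact probabilities with hydrophobic Phe334/Tyr772 contacts for
about 80% of inhibitors. Because the score models are Gaussian, the Bayes-
optimal threshold and error rates exist in closed form and serve as oracles
for the fitted classifiers.

What this does NOT emulate: correlated descriptors, multimodal score
distributions, pose-level noise, or activity cliffs — parameter-recovery
results here bound behavior under the stated model only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path


import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .labels import HIGHER_IS_INHIBITOR, INHIBITOR, LOWER_IS_INHIBITOR, NON_INHIBITOR
from .plif import InteractionRecord
from .score_models import DEFAULT_ORIENTATIONS, ScoreTable

__all__ = [
    "GeneratorConfig",
    "SyntheticDataset",
    "generate",
    "bayes_optimal_metrics",
    "default_scenario",
    "SMILES_POOL",
]

#: Small pool of real drug structures backing the descriptor / network demos.
SMILES_POOL = [
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O"),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C"),
    ("ibuprofen", "CC(C)Cc1ccc(C(C)C(=O)O)cc1"),
    ("naproxen", "COc1ccc2cc(C(C)C(=O)O)ccc2c1"),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1"),
    ("benzylpenicillin", "CC1(C)S[C@@H]2[C@H](NC(=O)Cc3ccccc3)C(=O)N2[C@H]1C(=O)O"),
    ("diazepam", "CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O"),
    ("warfarin", "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O"),
    ("propranolol", "CC(C)NCC(O)COc1cccc2ccccc12"),
    ("atenolol", "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1"),
    ("glibenclamide", "COc1ccc(Cl)cc1C(=O)NCCc1ccc(S(=O)(=O)NC(=O)NC2CCCCC2)cc1"),
    ("troglitazone", "Cc1c(C)c2c(c(C)c1O)CCC(C)(COc1ccc(CC3SC(=O)NC3=O)cc1)O2"),
    ("rosiglitazone", "CN(CCOc1ccc(CC2SC(=O)NC2=O)cc1)c1ccccn1"),
    ("pioglitazone", "CCc1ccc(CCOc2ccc(CC3SC(=O)NC3=O)cc2)nc1"),
    ("ketoconazole", "CC(=O)N1CCN(c2ccc(OCC3COC(Cn4ccnc4)(c4ccc(Cl)cc4Cl)O3)cc2)CC1"),
    ("nifedipine", "COC(=O)C1=C(C)NC(C)=C(C(=O)OC)C1c1ccccc1[N+](=O)[O-]"),
    ("verapamil", "COc1ccc(CCN(C)CCCC(C#N)(C(C)C)c2ccc(OC)c(OC)c2)cc1OC"),
    ("quinidine", "C=CC1CC2CCC1CN2CC(O)c1ccnc2ccc(OC)cc12"),
    ("simvastatin", "CCC(C)(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21"),
    ("lovastatin", "CCC(C)C(=O)OC1CC(C)C=C2C=CC(C)C(CCC3CC(O)CC(=O)O3)C21"),
    ("indomethacin", "COc1ccc2c(c1)c(CC(=O)O)c(C)n2C(=O)c1ccc(Cl)cc1"),
    ("sulfamethoxazole", "Cc1cc(NS(=O)(=O)c2ccc(N)cc2)no1"),
    ("cimetidine", "CC1=C(CSCCNC(=NC)NC#N)N=CN1"),
    ("ranitidine", "CNC(=C[N+](=O)[O-])NCCSCc1ccc(CN(C)C)o1"),
    ("metformin", "CN(C)C(=N)NC(=N)N"),
    ("chlorpromazine", "CN(C)CCCN1c2ccccc2Sc2ccc(Cl)cc21"),
    ("haloperidol", "O=C(CCCN1CCC(O)(c2ccc(Cl)cc2)CC1)c1ccc(F)cc1"),
    ("fluoxetine", "CNCCC(Oc1ccc(C(F)(F)F)cc1)c1ccccc1"),
    ("erythromycin_core", "CCC(=O)OC1CC(C)C(O)C(C)C1O"),
    ("ursodiol", "CC(CCC(=O)O)C1CCC2C3C(O)CC4CC(O)CCC4(C)C3CCC12C"),
]


def _default_score_params() -> dict:
    return {
        "ChemScore": {INHIBITOR: (37.5, 5.0), NON_INHIBITOR: (25.0, 7.0)},
        "GoldScore": {INHIBITOR: (60.0, 10.0), NON_INHIBITOR: (47.0, 11.0)},
        "GlideXP": {INHIBITOR: (-8.5, 1.5), NON_INHIBITOR: (-5.5, 1.8)},
        "XScore": {INHIBITOR: (6.6, 0.55), NON_INHIBITOR: (5.6, 0.65)},
    }


def _default_fp_probs() -> dict:
    n_bits, n_biased = 166, 20
    inh = np.full(n_bits, 0.15)
    non = np.full(n_bits, 0.15)
    inh[:n_biased] = 0.60
    non[:n_biased] = 0.20
    return {INHIBITOR: inh, NON_INHIBITOR: non}


def _default_group_probs() -> dict:
    return {
        "halide": (0.60, 0.30),
        "ether": (0.65, 0.40),
        "carbonyl": (0.80, 0.55),
        "vinyl_carbon": (0.50, 0.25),
        "amide": (0.60, 0.30),
        "arene": (0.95, 0.85),
        "hydroxyl": (0.45, 0.55),
        "carboxylic_acid": (0.15, 0.30),
    }


def _default_interaction_probs() -> dict:
    return {
        ("Phe334", "hydrophobic"): (0.80, 0.30),
        ("Tyr772", "hydrophobic"): (0.80, 0.35),
        ("Leu364", "hydrophobic"): (0.70, 0.30),
        ("Phe776", "hydrophobic"): (0.65, 0.30),
        ("Leu1026", "hydrophobic"): (0.65, 0.30),
        ("Tyr337", "hbond_donor"): (0.35, 0.50),
        ("Asn996", "hbond_acceptor"): (0.30, 0.55),
        ("Thr211", "hbond_donor"): (0.25, 0.45),
        ("Arg1001", "ionic"): (0.10, 0.20),
        ("Leu339", "surface_contact"): (0.50, 0.40),
    }

#: Ligand moiety emitted with each interaction type in synthetic records.
_GROUP_FOR_TYPE = {
    "hydrophobic": "arene",
    "hbond_donor": "hydroxyl",
    "hbond_acceptor": "carbonyl",
    "ionic": "carboxylic_acid",
    "surface_contact": "alkyl_carbon",
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters for the synthetic panel."""

    n_inhibitors: int = 113
    n_non_inhibitors: int = 295
    score_params: dict = field(default_factory=_default_score_params)
    mw_params: dict = field(default_factory=lambda: {
        INHIBITOR: (480.0, 80.0), NON_INHIBITOR: (300.0, 80.0)})
    logp_params: dict = field(default_factory=lambda: {
        INHIBITOR: (4.6, 1.5), NON_INHIBITOR: (2.6, 1.5)})
    fingerprint_bit_probs: dict = field(default_factory=_default_fp_probs)
    group_probs: dict = field(default_factory=_default_group_probs)
    interaction_probs: dict = field(default_factory=_default_interaction_probs)
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_inhibitors <= 0:
            problems.append("n_inhibitors must be > 0")
        if self.n_non_inhibitors <= 0:
            problems.append("n_non_inhibitors must be > 0")
        for name, params in ({"mw_params": self.mw_params,
                              "logp_params": self.logp_params} |
                             {f"score_params[{fn}]": p for fn, p in self.score_params.items()}).items():
            for cls in (INHIBITOR, NON_INHIBITOR):
                mean, sd = params[cls]
                if not sd > 0:
                    problems.append(f"{name}: sd for {cls} must be > 0")
        for cls, probs in self.fingerprint_bit_probs.items():
            p = np.asarray(probs, dtype=float)
            if ((p < 0) | (p > 1)).any():
                problems.append(f"fingerprint_bit_probs[{cls}] outside [0, 1]")
        for table_name, table in (("group_probs", self.group_probs),
                                  ("interaction_probs", self.interaction_probs)):
            for key, (p_inh, p_non) in table.items():
                if not (0 <= p_inh <= 1 and 0 <= p_non <= 1):
                    problems.append(f"{table_name}[{key}] outside [0, 1]")
        if problems:
            raise ValueError("invalid generator config: " + "; ".join(problems))

    def to_yaml(self, path) -> None:
        payload = {
            "n_inhibitors": self.n_inhibitors,
            "n_non_inhibitors": self.n_non_inhibitors,
            "seed": self.seed,
            "score_params": {fn: {cls: list(v) for cls, v in p.items()}
                             for fn, p in self.score_params.items()},
            "mw_params": {cls: list(v) for cls, v in self.mw_params.items()},
            "logp_params": {cls: list(v) for cls, v in self.logp_params.items()},
            "fingerprint_bit_probs": {cls: np.asarray(v, dtype=float).tolist()
                                      for cls, v in self.fingerprint_bit_probs.items()},
            "group_probs": {k: list(v) for k, v in self.group_probs.items()},
            "interaction_probs": {f"{res}|{itype}": list(v)
                                  for (res, itype), v in self.interaction_probs.items()},
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        raw = yaml.safe_load(Path(path).read_text())
        known = {"n_inhibitors", "n_non_inhibitors", "seed", "score_params", "mw_params",
                 "logp_params", "fingerprint_bit_probs", "group_probs", "interaction_probs"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown generator config keys: {sorted(unknown)}")
        kwargs = {k: raw[k] for k in ("n_inhibitors", "n_non_inhibitors", "seed") if k in raw}
        if "score_params" in raw:
            kwargs["score_params"] = {fn: {cls: tuple(v) for cls, v in p.items()}
                                      for fn, p in raw["score_params"].items()}
        for key in ("mw_params", "logp_params"):
            if key in raw:
                kwargs[key] = {cls: tuple(v) for cls, v in raw[key].items()}
        if "fingerprint_bit_probs" in raw:
            kwargs["fingerprint_bit_probs"] = {cls: np.asarray(v, dtype=float)
                                               for cls, v in raw["fingerprint_bit_probs"].items()}
        if "group_probs" in raw:
            kwargs["group_probs"] = {k: tuple(v) for k, v in raw["group_probs"].items()}
        if "interaction_probs" in raw:
            kwargs["interaction_probs"] = {tuple(k.split("|")): tuple(v)
                                           for k, v in raw["interaction_probs"].items()}
        return cls(**kwargs)


@dataclass
class SyntheticDataset:
    """All tables emitted for one synthetic panel, keyed by shared compound ids."""

    compounds: pd.DataFrame
    scores: ScoreTable
    descriptors: pd.DataFrame
    fingerprints: pd.DataFrame
    groups: pd.DataFrame
    interactions: list

    @property
    def labels(self) -> pd.Series:
        return self.compounds.set_index("id")["label"]


def generate(config: GeneratorConfig, with_smiles: bool = False) -> SyntheticDataset:
    """Draw one synthetic panel under the configured class-conditional model.

    Identical config (including seed) gives identical output. With
    ``with_smiles`` each compound also carries a real structure from the
    built-in pool (cycled), for descriptor and network demonstrations; the
    tabulated MW/logP remain the generated values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_inh, n_non = config.n_inhibitors, config.n_non_inhibitors
    n = n_inh + n_non
    ids = [f"INH{i:04d}" for i in range(n_inh)] + [f"NON{i:04d}" for i in range(n_non)]
    labels = np.array([INHIBITOR] * n_inh + [NON_INHIBITOR] * n_non, dtype=object)
    inh_mask = labels == INHIBITOR

    ic50 = np.empty(n)
    ic50[inh_mask] = 10.0 ** rng.uniform(-1.0, 1.0, n_inh)      # 0.1 .. 10 uM
    ic50[~inh_mask] = 10.0 ** rng.uniform(2.48, 3.5, n_non)     # > 300 uM
    compounds = pd.DataFrame({
        "id": ids, "label": labels, "mean_ic50_um": ic50,
        "pic50": 6.0 - np.log10(ic50),
    })
    if with_smiles:
        compounds["smiles"] = [SMILES_POOL[i % len(SMILES_POOL)][1] for i in range(n)]

    def draw_two_class(params) -> np.ndarray:
        out = np.empty(n)
        m, s = params[INHIBITOR]
        out[inh_mask] = rng.normal(m, s, n_inh)
        m, s = params[NON_INHIBITOR]
        out[~inh_mask] = rng.normal(m, s, n_non)
        return out

    score_rows = []
    for fn in sorted(config.score_params):
        vals = draw_two_class(config.score_params[fn])
        score_rows.append(pd.DataFrame({
            "compound_id": ids, "scoring_function": fn, "score": vals}))
    scores = ScoreTable(pd.concat(score_rows, ignore_index=True),
                        {fn: DEFAULT_ORIENTATIONS.get(fn, HIGHER_IS_INHIBITOR)
                         for fn in config.score_params})

    descriptors = pd.DataFrame({
        "id": ids,
        "mw": np.maximum(draw_two_class(config.mw_params), 30.0),
        "logp": draw_two_class(config.logp_params),
    })

    fp_cols = {}
    p_inh = np.asarray(config.fingerprint_bit_probs[INHIBITOR], dtype=float)
    p_non = np.asarray(config.fingerprint_bit_probs[NON_INHIBITOR], dtype=float)
    fp = np.empty((n, p_inh.size), dtype=np.uint8)
    fp[inh_mask] = rng.random((n_inh, p_inh.size)) < p_inh
    fp[~inh_mask] = rng.random((n_non, p_non.size)) < p_non
    fingerprints = pd.DataFrame(fp, index=ids,
                                columns=[f"bit{i}" for i in range(p_inh.size)])

    grp = {}
    for name, (pi, pn) in config.group_probs.items():
        col = np.empty(n, dtype=bool)
        col[inh_mask] = rng.random(n_inh) < pi
        col[~inh_mask] = rng.random(n_non) < pn
        grp[name] = col
    groups = pd.DataFrame(grp, index=ids)

    interactions = []
    for (residue, itype), (pi, pn) in config.interaction_probs.items():
        present = np.empty(n, dtype=bool)
        present[inh_mask] = rng.random(n_inh) < pi
        present[~inh_mask] = rng.random(n_non) < pn
        strengths = rng.uniform(0.25, 1.0, n)
        for i in np.flatnonzero(present):
            interactions.append(InteractionRecord(
                compound_id=ids[i], residue=residue, interaction_type=itype,
                functional_group=_GROUP_FOR_TYPE[itype], strength=float(strengths[i]),
            ))

    return SyntheticDataset(compounds=compounds, scores=scores, descriptors=descriptors,
                            fingerprints=fingerprints, groups=groups,
                            interactions=interactions)


def _gaussian_crossing(m_inh: float, s_inh: float, m_non: float, s_non: float) -> float:
    """Score where the two class-normalized normal densities are equal."""
    if m_inh == m_non and s_inh == s_non:
        raise ValueError("identical class distributions have no decision boundary")
    if s_inh == s_non:
        return (m_inh + m_non) / 2.0
    a = 1.0 / s_non ** 2 - 1.0 / s_inh ** 2
    b = -2.0 * (m_non / s_non ** 2 - m_inh / s_inh ** 2)
    c = (m_non ** 2 / s_non ** 2 - m_inh ** 2 / s_inh ** 2
         - 2.0 * math.log(s_inh / s_non))
    disc = b * b - 4 * a * c
    roots = [(-b + sign * math.sqrt(max(disc, 0.0))) / (2 * a) for sign in (+1, -1)]
    lo, hi = sorted((m_inh, m_non))
    inside = [r for r in roots if lo <= r <= hi]
    if inside:
        return inside[0]
    mid = (m_inh + m_non) / 2.0
    return min(roots, key=lambda r: abs(r - mid))


def bayes_optimal_metrics(config: GeneratorConfig, scoring_function: str) -> dict:
    """Closed-form optimum for a Gaussian scoring function in the config.

    Returns the class-density crossing threshold and the sensitivity,
    specificity and G-mean of thresholding there, in the scoring function's
    declared orientation.
    """
    params = config.score_params[scoring_function]
    m_inh, s_inh = params[INHIBITOR]
    m_non, s_non = params[NON_INHIBITOR]
    t = _gaussian_crossing(m_inh, s_inh, m_non, s_non)
    orientation = DEFAULT_ORIENTATIONS.get(scoring_function, HIGHER_IS_INHIBITOR)
    if orientation == LOWER_IS_INHIBITOR:
        sens = norm.cdf(t, m_inh, s_inh)
        spec = norm.sf(t, m_non, s_non)
    else:
        sens = norm.sf(t, m_inh, s_inh)
        spec = norm.cdf(t, m_non, s_non)
    return {"threshold": float(t), "orientation": orientation,
            "sensitivity": float(sens), "specificity": float(spec),
            "gmean": float(math.sqrt(sens * spec))}


def default_scenario() -> GeneratorConfig:
    """The out-of-the-box study conditions (113 inhibitors, 295 non-inhibitors)."""
    return GeneratorConfig()
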