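"""Synthetic compound libraries with planted structure-activity signal.

The generator emulates a curated TPO-inhibition activity table: each
compound is assembled from a template grammar (carbocyclic aromatic
scaffolds with 1-5 substitution slots filled by motif or inert decorator
fragments), so every emitted SMILES is valid chemistry and motif presence is
known exactly.  Activity is planted through the motifs:

* a quaternary class (A1/A2/B/C) is drawn from the target class mix;
* motif presence is sampled per class — active classes (A1/A2/B) use the
  motif's active prevalence, the inactive class C its inactive prevalence,
  and an active compound is guaranteed at least one potentiating motif
  (activity without any structural cause would be unlearnable noise);
* for A1/A2 compounds a latent ``log10 IC50 = baseline + sum(effect sizes of
  present motifs) + N(0, noise_sd)`` is drawn, truncated to the class band
  (<= 10 uM for A1, > 10 uM for A2);
* Hill-curve plateaus are drawn inside the band implied by the class
  (actives bottom out below 50 % of control activity, moderates between 50
  and 80, inactives above 80; top plateau near 100, slope jittered around 1)
  and the reported AC50 is the **exact inverse** of the IC50 conversion, so
  curation recovers the planted IC50 to rounding error.

A sidecar truth table records ground-truth motif presence and the latent
class, enabling oracle checks of the SMARTS-based frequency analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from rdkit import Chem
from scipy.stats import truncnorm

from .curation import invert_ic50_to_ac50

__all__ = [
    "SyntheticSpec",
    "generate_library",
    "expected_frequency",
    "MOTIF_DECORATORS",
    "DEFAULT_MOTIF_PREVALENCE",
    "DEFAULT_EFFECT_SIZE",
    "DEFAULT_CLASS_MIX",
]

# Scaffold templates: aromatic carbocycles with format-string substitution
# slots.  All slots sit on aromatic carbons so that amine/phenol/ether
# decorators land in their alert context (e.g. N on c -> primary aromatic
# amine).
_TEMPLATES: list[str] = [
    "c1ccc({0})cc1",
    "c1ccc2cc({0})ccc2c1",
    "c1ccc(-c2ccc({0})cc2)cc1",
    "C1CCC(CC1)c1ccc({0})cc1",
    "c1cc({0})ccc1{1}",
    "c1ccc({0})c({1})c1",
    "c1ccc2c(c1)cc({0})c(c2){1}",
    "c1cc({0})cc({1})c1{2}",
    "c1ccc(-c2cc({0})cc({1})c2{2})cc1",
    "c1c({0})cc({1})c({2})c1{3}",
    "c1c({0})c({1})c({2})c({3})c1{4}",
]

# Decorator SMILES fragment per motif, valid as a branch on an aromatic carbon.
MOTIF_DECORATORS: dict[str, str] = {
    "primary_aromatic_amine": "N",
    "phenol": "O",
    "enol_ether": "OC=C",
    "thioether": "SC",
    "phosphate_ester": "OP(=O)(OC)OC",
}

# Inert decorators: halogens and alkyl groups that match none of the bundled
# chemotype patterns.
_INERT_DECORATORS: list[str] = [
    "C", "CC", "CCC", "CCCC", "C(C)C", "C(C)(C)C", "C(C)CC",
    "Cl", "F", "Br", "C(F)(F)F", "C#N",
]

# Active/inactive prevalence per motif.  The aromatic amine is the dominant
# planted alert (strong prevalence contrast); the remaining motifs are mildly
# enriched, mirroring an alert hierarchy with one dominant toxicophore.
DEFAULT_MOTIF_PREVALENCE: dict[str, tuple[float, float]] = {
    "primary_aromatic_amine": (0.80, 0.05),
    "phenol": (0.28, 0.08),
    "enol_ether": (0.24, 0.07),
    "thioether": (0.22, 0.07),
    "phosphate_ester": (0.15, 0.05),
}

# Shift in log10 IC50 (uM) per present motif; negative = potentiating.
DEFAULT_EFFECT_SIZE: dict[str, float] = {
    "primary_aromatic_amine": -1.5,
    "phenol": -0.8,
    "enol_ether": -0.7,
    "thioether": -0.6,
    "phosphate_ester": -0.5,
}

# Target quaternary class fractions, mirroring a strongly imbalanced curated
# assay dataset (actives dominate; true inactives are the minority).
DEFAULT_CLASS_MIX: dict[str, float] = {"A1": 0.21, "A2": 0.39, "B": 0.22, "C": 0.18}

_ACTIVE_CLASSES = ("A1", "A2", "B")


@dataclass
class SyntheticSpec:
    """Configuration of one synthetic library.

    ``motif_prevalence`` maps motif name to ``(p_active, p_inactive)``:
    the per-compound presence probability in the binary-active classes
    (A1/A2/B) and in the inactive class C.  ``effect_size`` shifts the latent
    log10 IC50 per present motif.  ``noise_sd`` is the sd of the log10 IC50
    noise; ``curve_noise`` the sd (in % response) of the plateau jitter.
    """

    n_compounds: int = 600
    motif_prevalence: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_MOTIF_PREVALENCE)
    )
    effect_size: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZE))
    class_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    noise_sd: float = 0.4
    curve_noise: float = 2.0
    baseline_log_ic50: float = 2.0  # 100 uM: an undecorated scaffold is weak
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds <= 0:
            raise ValueError("n_compounds must be positive")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        for motif, (pa, pi) in self.motif_prevalence.items():
            if motif not in MOTIF_DECORATORS:
                raise ValueError(f"unknown motif {motif!r}; choose from {sorted(MOTIF_DECORATORS)}")
            if not (0 <= pa <= 1 and 0 <= pi <= 1):
                raise ValueError(f"prevalences for {motif!r} must lie in [0, 1]")


def _class_counts(spec: SyntheticSpec) -> dict[str, int]:
    """Largest-remainder allocation of compounds to classes."""
    shares = {c: spec.n_compounds * frac for c, frac in spec.class_mix.items()}
    counts = {c: int(math.floor(s)) for c, s in shares.items()}
    rest = spec.n_compounds - sum(counts.values())
    order = sorted(spec.class_mix, key=lambda c: (counts[c] - shares[c], c))
    for c in order[:rest]:
        counts[c] += 1
    infeasible = [c for c, frac in spec.class_mix.items() if frac > 0 and counts[c] == 0]
    if infeasible:
        raise ValueError(f"class_mix infeasible for n={spec.n_compounds}: empty classes {infeasible}")
    return counts


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _assemble_smiles(
    rng: np.random.Generator, present: list[str], seen: set[str]
) -> tuple[str, str] | None:
    """One attempt at a novel scaffold + decorator assembly; None on collision."""
    eligible = [t for t in _TEMPLATES if t.count("{") >= max(1, len(present))]
    template = eligible[rng.integers(len(eligible))]
    n_slots = template.count("{")
    decorators = [MOTIF_DECORATORS[m] for m in present]
    while len(decorators) < n_slots:
        decorators.append(_INERT_DECORATORS[rng.integers(len(_INERT_DECORATORS))])
    perm = rng.permutation(len(decorators))
    smiles = template.format(*[decorators[i] for i in perm])
    canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
    if canonical in seen:
        return None
    return smiles, canonical


def generate_library(
    spec: SyntheticSpec,
    out_csv=None,
    truth_csv=None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an activity table (curation input schema) plus a truth table.

    Returns ``(activity, truth)`` DataFrames and optionally writes them as
    CSV.  The activity table has columns ``id,name,smiles,max_inhibition,
    a,b,c,ac50,ic50,source`` (``ic50`` left blank — curation re-derives it
    from AC50); the truth table records planted motif presence, latent class
    labels and the planted log10 IC50.
    """
    rng = np.random.default_rng(spec.seed)
    motifs = list(spec.motif_prevalence)
    counts = _class_counts(spec)
    classes = [c for c, k in sorted(counts.items()) for _ in range(k)]
    classes = [classes[i] for i in rng.permutation(len(classes))]

    seen: set[str] = set()
    activity_rows, truth_rows = [], []
    for i, cls in enumerate(classes):
        is_active = cls in _ACTIVE_CLASSES
        # motif presence; actives are guaranteed at least one potentiating motif
        for _ in range(100):
            present = [
                m
                for m in motifs
                if rng.random() < spec.motif_prevalence[m][0 if is_active else 1]
            ]
            if present or not is_active:
                break
        else:  # pragma: no cover - probability ~0 under sane prevalences
            present = ["primary_aromatic_amine"]

        for _ in range(500):
            assembled = _assemble_smiles(rng, present, seen)
            if assembled is not None:
                break
        else:
            raise RuntimeError("could not assemble a novel structure; library too large for the grammar")
        smiles, canonical = assembled
        seen.add(canonical)

        # Hill-curve plateaus inside the class band (max inhibition = 100 - a)
        if is_active and cls != "B":
            a_resp = float(rng.uniform(5, 45))
        elif cls == "B":
            a_resp = float(rng.uniform(53, 77))
        else:
            a_resp = float(rng.uniform(83, 99))
        a_resp += float(rng.normal(0, spec.curve_noise))
        # active-class bottom plateaus stay clear of 50 % so the Hill factor
        # keeps the log-domain AC50 inversion within floating-point range
        lo, hi = {"A1": (5, 45), "A2": (5, 45), "B": (50.2, 79.8), "C": (80.3, 99.9)}[cls]
        a_resp = float(np.clip(a_resp, lo, hi))
        b_resp = float(np.clip(100 + rng.normal(0, spec.curve_noise), 92, 108))
        c_slope = float(np.clip(np.exp(rng.normal(0, 0.2)), 0.6, 1.8))

        log_ic50 = None
        ac50 = None
        if cls in ("A1", "A2"):
            mu = spec.baseline_log_ic50 + sum(spec.effect_size.get(m, 0.0) for m in present)
            if cls == "A1":
                log_ic50 = _truncated_normal(rng, mu, spec.noise_sd, -4.0, 1.0)
            else:
                log_ic50 = _truncated_normal(rng, mu, spec.noise_sd, 1.0 + 1e-6, 4.0)
            ac50 = invert_ic50_to_ac50(10.0**log_ic50, a_resp, b_resp, c_slope, mode="log")

        cid = f"syn-{i:04d}"
        activity_rows.append(
            {
                "id": cid,
                "name": cid,
                "smiles": smiles,
                "max_inhibition": round(100.0 - a_resp, 6),
                "a": round(a_resp, 6),
                "b": round(b_resp, 6),
                "c": round(c_slope, 6),
                "ac50": ac50 if ac50 is None else float(f"{ac50:.10g}"),
                "ic50": None,
                "source": "synthetic",
            }
        )
        truth_rows.append(
            {
                "id": cid,
                "smiles": canonical,
                "quaternary": cls,
                "ternary": "A" if cls in ("A1", "A2") else cls,
                "binary": "A" if is_active else "C",
                "log10_ic50": None if log_ic50 is None else round(log_ic50, 6),
                **{f"motif_{m}": int(m in present) for m in motifs},
            }
        )

    activity = pd.DataFrame(activity_rows)
    truth = pd.DataFrame(truth_rows)
    if out_csv is not None:
        activity.to_csv(out_csv, index=False)
    if truth_csv is not None:
        truth.to_csv(truth_csv, index=False)
    return activity, truth


def expected_frequency(truth: pd.DataFrame, group_col: str = "quaternary") -> pd.DataFrame:
    """Oracle frequency table computed from truth motif-presence columns.

    Direct counting on the ``motif_*`` columns — no SMARTS matching — with the
    same ``(f_x * C) / (f * C_x)`` statistic and an ``A1``/``C`` ratio.  Used
    to validate the SMARTS-based frequency analysis.
    """
    motif_cols = [c for c in truth.columns if c.startswith("motif_")]
    C = len(truth)
    groups = sorted(truth[group_col].unique())
    rows = {}
    for col in motif_cols:
        key = col[len("motif_"):]
        f = int((truth[col] > 0).sum())
        row: dict[str, float] = {"f": f, "C": C}
        for g in groups:
            sub = truth[truth[group_col] == g]
            f_x = int((sub[col] > 0).sum())
            C_x = len(sub)
            row[f"f_{g}"] = f_x
            row[f"C_{g}"] = C_x
            row[f"freq_{g}"] = (f_x * C) / (f * C_x) if f > 0 else 0.0
        if "A1" in groups and "C" in groups:
            hi, lo = row["freq_A1"], row["freq_C"]
            row["ratio"] = hi / lo if lo > 0 else (math.inf if hi > 0 else 0.0)
        rows[key] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "key"
    return out
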