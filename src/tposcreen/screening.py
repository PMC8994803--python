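"""Consensus screening of candidate compound lists.

A candidate is flagged ``consensus_active`` when the binary model predicts
A, the ternary model predicts A, and the quaternary model predicts A1 — i.e.
all three per-grouping winners agree the compound is in the most active
class.  A principal-component bounding-box check over 2D descriptors gives
an advisory applicability-domain (chemical-space) flag: predictions for
compounds far outside the training chemical space should not be trusted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from .features import FeatureMatrix, descriptor_table
from .modeling import MinMaxVarianceScaler, ModelBundle, _SignFixedPCA

__all__ = ["screen_compounds", "chemical_space_check", "ChemicalSpaceResult"]

_EXPECTED_PREDICTION = {"binary": "A", "ternary": "A", "quaternary": "A1"}


def screen_compounds(
    bundles: Mapping[str, ModelBundle],
    candidates: Sequence[tuple[str, str]],
    annotations: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Apply the three per-grouping winners to a candidate list.

    ``bundles`` maps ``binary``/``ternary``/``quaternary`` to trained
    :class:`~tposcreen.modeling.ModelBundle` objects; ``candidates`` is a list
    of ``(id, smiles)``.  Unparseable candidates are excluded and reported.
    An optional ``annotations`` frame (indexed by id, e.g. an externally
    computed Cramer class) is joined onto the report.

    Returns ``(report, errors)`` where the report has one row per screened
    candidate with per-grouping predictions and the consensus flag.
    """
    for grouping in ("binary", "ternary", "quaternary"):
        if grouping not in bundles:
            raise ValueError(f"missing model bundle for grouping {grouping!r}")
        bundle = bundles[grouping]
        if bundle.recipe.feature_set_id != bundle.feature_set:
            raise ValueError(
                f"feature-set mismatch in {grouping} bundle: recipe produces "
                f"{bundle.recipe.feature_set_id!r} but bundle was trained on {bundle.feature_set!r}"
            )

    errors: list[str] = []
    ids, smiles = [], []
    for cid, smi in candidates:
        if not isinstance(smi, str) or Chem.MolFromSmiles(smi) is None:
            errors.append(f"{cid}: unparseable SMILES {smi!r}")
            continue
        ids.append(str(cid))
        smiles.append(smi)

    report = pd.DataFrame({"id": ids, "smiles": smiles}).set_index("id")
    for grouping in ("binary", "ternary", "quaternary"):
        bundle = bundles[grouping]
        feats = bundle.recipe.featurize(ids, smiles)
        report[f"pred_{grouping}"] = bundle.model.predict(feats.values)
    report["consensus_active"] = (
        (report["pred_binary"] == "A")
        & (report["pred_ternary"] == "A")
        & (report["pred_quaternary"] == "A1")
    )
    if annotations is not None:
        annotations = annotations.copy()
        annotations.index = annotations.index.astype(str)
        report = report.join(annotations, how="left")
    return report.reset_index(), errors


@dataclass
class ChemicalSpaceResult:
    """Advisory applicability-domain check in principal-component space."""

    in_domain: np.ndarray  # bool per candidate
    train_coords: np.ndarray  # n_train x n_components
    candidate_coords: np.ndarray  # n_candidates x n_components
    lower: np.ndarray
    upper: np.ndarray


def chemical_space_check(
    train_descriptors: FeatureMatrix | np.ndarray,
    candidate_descriptors: FeatureMatrix | np.ndarray,
    n_components: int = 3,
    margin: float = 0.1,
    seed: int = 0,
) -> ChemicalSpaceResult:
    """Bounding-box applicability check in training PC space.

    Descriptors are min-max scaled (training statistics), projected onto
    ``n_components`` principal components fit on the training set, and a
    candidate is in-domain iff each of its PC scores lies within the training
    range expanded by ``margin`` (fraction of each PC's range) on both sides.
    This is an advisory flag, not a formal domain model.
    """
    Xt = train_descriptors.values if isinstance(train_descriptors, FeatureMatrix) else np.asarray(train_descriptors, float)
    Xc = candidate_descriptors.values if isinstance(candidate_descriptors, FeatureMatrix) else np.asarray(candidate_descriptors, float)
    if Xt.shape[1] != Xc.shape[1]:
        raise ValueError("training and candidate descriptor sets differ in width")
    if n_components > min(Xt.shape):
        raise ValueError(f"n_components={n_components} exceeds the rank bound {min(Xt.shape)}")
    scaler = MinMaxVarianceScaler(var_threshold=0.0).fit(Xt)
    Zt = scaler.transform(Xt)
    Zc = scaler.transform(Xc)
    pca = _SignFixedPCA(n_components, seed).fit(Zt)
    Tt = pca.transform(Zt)
    Tc = pca.transform(Zc)
    lo, hi = Tt.min(axis=0), Tt.max(axis=0)
    pad = margin * (hi - lo)
    in_domain = np.all((Tc >= lo - pad) & (Tc <= hi + pad), axis=1)
    return ChemicalSpaceResult(in_domain, Tt, Tc, lo - pad, hi + pad)
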