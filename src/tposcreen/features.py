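"""Molecular feature generation.

Three feature families feed the classifiers:

* **topological fingerprints** — hashed RDKit-path, Morgan (circular) and
  atom-pair-count vectors (the atom-pair fingerprint hashes
  (atom type, atom type, topological distance) triples into count slots using
  RDKit's stable atom-pair encoding, folded to a fixed width);
* **substructure-key fingerprints** — match counts against an ordered SMARTS
  chemotype library (a bundled structural-alert library is provided; any
  library in the same tab-separated format can be substituted);
* **2D molecular descriptors** — a fixed, documented RDKit descriptor set
  used for chemical-space (applicability) analysis.

A topological fingerprint concatenated column-wise with the substructure-key
block is the "``<topo>_Sub``" feature set used throughout the pipeline.
Every concatenated column name is prefixed with its source block, so column
provenance is recoverable from the name alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator, rdMolDescriptors

__all__ = [
    "SmartsEntry",
    "SmartsLibrary",
    "FeatureMatrix",
    "topological_fp",
    "substructure_key_fp",
    "concat_fp",
    "topological_matrix",
    "substructure_matrix",
    "descriptor_table",
    "FeatureRecipe",
    "read_smiles_file",
    "read_sdf",
    "read_candidates",
    "DESCRIPTOR_NAMES",
    "TOPO_KINDS",
]

TOPO_KINDS = ("rdkit_path", "morgan", "atom_pair_count")

_SET_IDS = {"rdkit_path": "RDKit", "morgan": "Morgan", "atom_pair_count": "APC"}


def _mol(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    return mol


@dataclass(frozen=True)
class SmartsEntry:
    key_name: str
    smarts: str
    count_mode: str = "occurrence"  # "presence" or "occurrence"

    def __post_init__(self):
        if self.count_mode not in ("presence", "occurrence"):
            raise ValueError(f"bad count mode {self.count_mode!r} for key {self.key_name}")
        if Chem.MolFromSmarts(self.smarts) is None:
            raise ValueError(f"SMARTS does not compile for key {self.key_name}: {self.smarts!r}")


class SmartsLibrary:
    """Ordered library of named SMARTS chemotypes; order fixes column order."""

    def __init__(self, entries: Sequence[SmartsEntry], name: str = "Sub"):
        names = [e.key_name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate key names in SMARTS library")
        self.entries: list[SmartsEntry] = list(entries)
        self.name = name
        self._patterns = [Chem.MolFromSmarts(e.smarts) for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def key_names(self) -> list[str]:
        return [e.key_name for e in self.entries]

    @classmethod
    def from_file(cls, path, name: str | None = None) -> "SmartsLibrary":
        """Load a tab-separated ``key_name<TAB>smarts<TAB>mode`` library file."""
        entries = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].lstrip().startswith("#"):
                    continue
                key, smarts = row[0].strip(), row[1].strip()
                mode = row[2].strip() if len(row) > 2 and row[2].strip() else "occurrence"
                entries.append(SmartsEntry(key, smarts, mode))
        return cls(entries, name=name or Path(path).stem)

    @classmethod
    def default(cls) -> "SmartsLibrary":
        """The bundled structural-alert chemotype library."""
        path = resources.files("tposcreen.data").joinpath("chemotypes.tsv")
        with resources.as_file(path) as p:
            lib = cls.from_file(p, name="chemotypes")
        return lib

    def match_counts(self, smiles: str) -> np.ndarray:
        """Vector of match counts (or 0/1 for presence-mode keys) per entry."""
        mol = _mol(smiles)
        out = np.zeros(len(self.entries), dtype=float)
        for i, (entry, pat) in enumerate(zip(self.entries, self._patterns)):
            matches = mol.GetSubstructMatches(pat, uniquify=True)
            out[i] = (1.0 if matches else 0.0) if entry.count_mode == "presence" else float(len(matches))
        return out


@dataclass
class FeatureMatrix:
    """Named feature columns for an ordered set of compounds."""

    compound_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    feature_set_id: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.compound_ids), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.compound_ids)} compounds x {len(self.feature_names)} features"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.feature_names)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path, feature_set_id: str) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            compound_ids=[str(i) for i in df.index],
            feature_names=list(df.columns),
            values=df.to_numpy(dtype=float),
            feature_set_id=feature_set_id,
        )

    def subset(self, ids: Sequence[str]) -> "FeatureMatrix":
        """Row subset in the order of ``ids``."""
        pos = {cid: i for i, cid in enumerate(self.compound_ids)}
        idx = [pos[i] for i in ids]
        return FeatureMatrix(list(ids), list(self.feature_names), self.values[idx], self.feature_set_id)


_FP_GENERATORS: dict[tuple, object] = {}


def _generator(kind: str, n_bits: int, radius: int, max_path: int):
    key = (kind, n_bits, radius, max_path)
    if key not in _FP_GENERATORS:
        if kind == "morgan":
            gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        elif kind == "rdkit_path":
            gen = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=max_path, fpSize=n_bits)
        elif kind == "atom_pair_count":
            gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits)
        else:
            raise ValueError(f"unknown fingerprint kind {kind!r}; expected one of {TOPO_KINDS}")
        _FP_GENERATORS[key] = gen
    return _FP_GENERATORS[key]


def topological_fp(
    smiles: str,
    kind: str = "atom_pair_count",
    *,
    n_bits: int = 2048,
    radius: int = 2,
    max_path: int = 7,
    counts: bool | None = None,
) -> np.ndarray:
    """Hashed topological fingerprint of one molecule.

    ``atom_pair_count`` always yields counts; Morgan and RDKit-path default to
    bit vectors (``counts=True`` switches them to count vectors).  Defaults:
    Morgan radius 2, RDKit path length 7, 2048 slots.
    """
    mol = _mol(smiles)
    gen = _generator(kind, n_bits, radius, max_path)
    as_counts = True if kind == "atom_pair_count" else bool(counts)
    vec = np.zeros(n_bits, dtype=float)
    if as_counts:
        for slot, count in gen.GetCountFingerprint(mol).GetNonzeroElements().items():
            vec[slot] = count
    else:
        for slot in gen.GetFingerprint(mol).GetOnBits():
            vec[slot] = 1.0
    return vec


def substructure_key_fp(smiles: str, library: SmartsLibrary) -> np.ndarray:
    """Substructure-key vector aligned to the library's entry order."""
    return library.match_counts(smiles)


def topological_matrix(
    ids: Sequence[str],
    smiles: Sequence[str],
    kind: str = "atom_pair_count",
    **params,
) -> FeatureMatrix:
    rows = np.stack([topological_fp(s, kind, **params) for s in smiles]) if len(smiles) else np.zeros((0, params.get("n_bits", 2048)))
    set_id = _SET_IDS[kind]
    names = [f"{set_id}:{i:04d}" for i in range(rows.shape[1])]
    return FeatureMatrix(list(map(str, ids)), names, rows, set_id)


def substructure_matrix(ids: Sequence[str], smiles: Sequence[str], library: SmartsLibrary | None = None) -> FeatureMatrix:
    library = library or SmartsLibrary.default()
    rows = np.stack([library.match_counts(s) for s in smiles]) if len(smiles) else np.zeros((0, len(library)))
    names = [f"sub:{k}" for k in library.key_names]
    return FeatureMatrix(list(map(str, ids)), names, rows, "Sub")


def concat_fp(topo: FeatureMatrix, sub: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation ``<topo>_Sub`` of a topological and a key block."""
    if topo.compound_ids != sub.compound_ids:
        raise ValueError("compound id mismatch between fingerprint blocks")
    return FeatureMatrix(
        compound_ids=list(topo.compound_ids),
        feature_names=list(topo.feature_names) + list(sub.feature_names),
        values=np.hstack([topo.values, sub.values]),
        feature_set_id=f"{topo.feature_set_id}_Sub",
    )


# Fixed 2D descriptor set for the descriptor table / chemical-space analysis.
DESCRIPTOR_NAMES = [
    "MolWt",
    "HeavyAtomCount",
    "MolLogP",
    "TPSA",
    "NumHDonors",
    "NumHAcceptors",
    "NumRotatableBonds",
    "RingCount",
    "NumAromaticRings",
    "FractionCSP3",
    "Chi0v",
    "Chi1v",
    "Kappa1",
    "Kappa2",
    "BertzCT",
    "LabuteASA",
]

_DESCRIPTOR_FNS = {name: fn for name, fn in Descriptors.descList if name in DESCRIPTOR_NAMES}


def descriptor_table(smiles: Sequence[str], ids: Sequence[str] | None = None) -> FeatureMatrix:
    """Fixed 2D descriptor table; failed molecules get all-NaN rows."""
    ids = list(map(str, ids)) if ids is not None else [str(i) for i in range(len(smiles))]
    rows = np.full((len(smiles), len(DESCRIPTOR_NAMES)), np.nan)
    for r, smi in enumerate(smiles):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            continue
        for c, name in enumerate(DESCRIPTOR_NAMES):
            rows[r, c] = float(_DESCRIPTOR_FNS[name](mol))
    return FeatureMatrix(ids, list(DESCRIPTOR_NAMES), rows, "Descriptors")


@dataclass
class FeatureRecipe:
    """A reproducible featurization: topological kind + optional key library.

    Stored inside trained model bundles so that screening candidates are
    featurized exactly the way the training set was.
    """

    topo_kind: str = "atom_pair_count"
    n_bits: int = 2048
    radius: int = 2
    max_path: int = 7
    counts: bool | None = None
    with_sub: bool = True
    library: SmartsLibrary | None = None

    @property
    def feature_set_id(self) -> str:
        base = _SET_IDS[self.topo_kind]
        return f"{base}_Sub" if self.with_sub else base

    def featurize(self, ids: Sequence[str], smiles: Sequence[str]) -> FeatureMatrix:
        topo = topological_matrix(
            ids, smiles, self.topo_kind,
            n_bits=self.n_bits, radius=self.radius, max_path=self.max_path, counts=self.counts,
        )
        if not self.with_sub:
            return topo
        sub = substructure_matrix(ids, smiles, self.library)
        return concat_fp(topo, sub)


def read_smiles_file(path) -> list[tuple[str, str]]:
    """Read one-SMILES-per-line (optional whitespace-separated id) -> (id, smiles)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            smiles = parts[0]
            cid = parts[1] if len(parts) > 1 else f"line{i}"
            out.append((cid, smiles))
    return out


def read_sdf(path) -> list[tuple[str, str]]:
    """Read an SDF into (id, canonical SMILES); id from the molecule name."""
    out = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier, start=1):
        if mol is None:
            continue
        cid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"mol{i}"
        out.append((cid, Chem.MolToSmiles(mol)))
    return out


def read_candidates(path) -> list[tuple[str, str]]:
    """Read a candidate list from .smi/.txt, .sdf, or .csv (id,smiles columns)."""
    suffix = Path(path).suffix.lower()
    if suffix in (".smi", ".txt", ""):
        return read_smiles_file(path)
    if suffix == ".sdf":
        return read_sdf(path)
    if suffix == ".csv":
        df = pd.read_csv(path, dtype={"id": str})
        if "smiles" not in df.columns:
            raise ValueError(f"candidate CSV {path} needs a 'smiles' column")
        ids = df["id"].astype(str) if "id" in df.columns else [f"row{i}" for i in range(len(df))]
        return list(zip(ids, df["smiles"]))
    raise ValueError(f"unsupported candidate file type: {path}")
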