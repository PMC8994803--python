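"""Dose-response curation for TPO-inhibition activity tables.

The raw inputs are concentration-response records: per compound, a Hill-curve
fit (bottom plateau ``a``, top plateau ``b``, slope ``c``, all responses in %
of control enzyme activity), a relative half-maximal concentration AC50, and
the maximum inhibition reached at the highest tested concentration.  Curation

* standardizes structures (desalting, mixture rejection, deduplication),
* converts the relative AC50 into an absolute IC50 via the Hill-curve factor
  ``((a - 50) / (50 - b)) ** (1 / c)``, and
* assigns binary / ternary / quaternary activity classes from maximum
  inhibition and IC50.

Class conventions (all cutoffs inclusive as noted):

=========  =====================================  =================
grouping   class                                  criterion
=========  =====================================  =================
binary     A (active)                             max inhibition >= 20 %
           C (inactive)                           < 20 %
ternary    A                                      > 50 %
           B                                      20-50 % (inclusive)
           C                                      < 20 %
quaternary A1                                     ternary A and IC50 <= 10 uM
           A2                                     ternary A and IC50 > 10 uM
           B, C                                   as ternary
=========  =====================================  =================
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CompoundRecord",
    "DoseResponse",
    "ActivityLabelSet",
    "CurationError",
    "MixtureError",
    "NotConvertibleError",
    "CurationLog",
    "TableReadResult",
    "read_activity_table",
    "strip_salts_and_mixtures",
    "deduplicate",
    "hill_factor",
    "convert_ac50_to_ic50",
    "invert_ic50_to_ac50",
    "assign_labels",
    "curate_table",
]


class CurationError(ValueError):
    """Base class for structure-curation failures."""


class MixtureError(CurationError):
    """Raised when a multi-fragment input contains two or more organic parents."""


class NotConvertibleError(CurationError):
    """AC50 cannot be converted: the curve never crosses 50 % inhibition (a >= 50)."""


@dataclass
class CompoundRecord:
    """One curated chemical: identifier plus canonical structure."""

    id: str
    smiles: str
    name: str | None = None
    source: str | None = None


@dataclass
class DoseResponse:
    """Assay readout for one compound.

    ``a_min_response``/``b_max_response`` are the bottom/top plateaus of the
    Hill fit in % of control activity, ``c_slope`` the (positive) Hill slope.
    ``max_inhibition`` is ``100 - a`` when curve data are present.  ``ic50``
    is only meaningful when ``max_inhibition > 50``.
    """

    a_min_response: float | None = None
    b_max_response: float | None = None
    c_slope: float | None = None
    ac50: float | None = None
    max_inhibition: float | None = None
    ic50: float | None = None

    def completeness(self) -> int:
        """Number of set curve-data fields (used to rank duplicate records)."""
        return sum(
            v is not None
            for v in (self.a_min_response, self.b_max_response, self.c_slope, self.ac50, self.ic50)
        )


@dataclass(frozen=True)
class ActivityLabelSet:
    """Binary / ternary / quaternary class labels for one compound."""

    binary: str
    ternary: str
    quaternary: str

    def __post_init__(self) -> None:
        ok = (
            (self.binary == "A") == (self.ternary in ("A", "B"))
            and (self.ternary == "A") == (self.quaternary in ("A1", "A2"))
            and (self.ternary == "B") == (self.quaternary == "B")
            and (self.ternary == "C") == (self.quaternary == "C")
        )
        if not ok:
            raise ValueError(f"inconsistent label set {self}")


# Counter-ions recognised during salt stripping: common inorganic ions plus
# small organic acid/base counter-ions.  Neutral organic solvents are *not*
# listed, so a co-crystallised organic solvent makes the input a mixture.
_COUNTERION_SMILES = [
    "[Na+]", "[K+]", "[Li+]", "[Cs+]", "[Ca+2]", "[Mg+2]", "[Zn+2]", "[Ba+2]",
    "[Al+3]", "[Fe+2]", "[Fe+3]", "[NH4+]",
    "[Cl-]", "[Br-]", "[I-]", "[F-]", "[OH-]", "Cl", "Br", "I", "F",
    "O", "N",
    "[O-][N+](=O)O", "[O-][N+](=O)[O-]", "O[N+](=O)[O-]",
    "OS(=O)(=O)O", "[O-]S(=O)(=O)O", "[O-]S(=O)(=O)[O-]",
    "OP(=O)(O)O", "[O-]P(=O)(O)O",
    # small organic acid counter-ions (neutral and deprotonated forms)
    "CC(=O)O", "CC(=O)[O-]",
    "OC(=O)C(F)(F)F", "[O-]C(=O)C(F)(F)F",
    "CS(=O)(=O)O", "CS(=O)(=O)[O-]",
    "Cc1ccc(S(=O)(=O)O)cc1", "Cc1ccc(S(=O)(=O)[O-])cc1",
    "OC(=O)C(=O)O", "[O-]C(=O)C(=O)[O-]",
    "OC(=O)/C=C\\C(=O)O", "OC(=O)/C=C/C(=O)O", "OC(=O)C=CC(=O)O",
    "OC(=O)C(O)C(O)C(=O)O",
    "OC(=O)CC(O)(CC(=O)O)C(=O)O",
    "OC=O", "[O-]C=O",
    "OC(=O)c1ccccc1", "[O-]C(=O)c1ccccc1",
]


def _canonical(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CurationError(f"unparseable SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


COUNTERIONS: frozenset[str] = frozenset(_canonical(s) for s in _COUNTERION_SMILES)


def _has_carbon(mol: Chem.Mol) -> bool:
    return any(atom.GetAtomicNum() == 6 for atom in mol.GetAtoms())


def strip_salts_and_mixtures(smiles: str) -> str:
    """Return the canonical SMILES of the organic parent of ``smiles``.

    Single-fragment inputs are returned canonicalized.  For multi-fragment
    inputs the unique carbon-containing fragment is kept; carbon-free
    fragments and fragments on the bundled counter-ion list are treated as
    counter-ions/solvents.  Two or more organic fragments raise
    :class:`MixtureError`; an input with no organic fragment raises
    :class:`CurationError`.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise CurationError(f"unparseable SMILES: {smiles!r}")
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        return Chem.MolToSmiles(mol)
    carbon_frags = [f for f in frags if _has_carbon(f)]
    if not carbon_frags:
        raise CurationError(f"no organic fragment in {smiles!r}")
    if len(carbon_frags) == 1:
        return Chem.MolToSmiles(carbon_frags[0])
    organic = [f for f in carbon_frags if Chem.MolToSmiles(f) not in COUNTERIONS]
    if len(organic) == 1:
        return Chem.MolToSmiles(organic[0])
    raise MixtureError(f"multiple organic fragments in {smiles!r}")


def hill_factor(a: float, b: float, c: float) -> float:
    """Hill-curve scaling factor ``((a - 50) / (50 - b)) ** (1 / c)``.

    Requires a curve that actually crosses 50 % response: bottom plateau
    ``a < 50`` and top plateau ``b > 50``.
    """
    if c <= 0:
        raise ValueError(f"slope factor must be positive, got {c}")
    if b <= 50:
        raise ValueError(f"invalid curve: top plateau b={b} must exceed 50 % response")
    if a >= 50:
        raise NotConvertibleError(
            f"curve never reaches 50 % inhibition (bottom plateau a={a} >= 50)"
        )
    return ((a - 50.0) / (50.0 - b)) ** (1.0 / c)


def convert_ac50_to_ic50(
    ac50: float, a: float, b: float, c: float, mode: str = "log"
) -> float:
    """Convert a relative AC50 (uM) to an absolute IC50 (uM).

    ``mode="log"`` (default) scales log10(AC50) by the Hill factor:
    ``log10(IC50) = log10(AC50) * factor``.  ``mode="linear"`` scales the
    concentration itself: ``IC50 = AC50 * factor``.  Both agree on a
    full-range curve (a=0, b=100, c arbitrary), where the factor is exactly 1.
    """
    if ac50 <= 0:
        raise ValueError(f"AC50 must be positive, got {ac50}")
    factor = hill_factor(a, b, c)
    if mode == "log":
        return 10.0 ** (math.log10(ac50) * factor)
    if mode == "linear":
        return ac50 * factor
    raise ValueError(f"unknown conversion mode {mode!r}")


def invert_ic50_to_ac50(
    ic50: float, a: float, b: float, c: float, mode: str = "log"
) -> float:
    """Exact inverse of :func:`convert_ac50_to_ic50` (same mode conventions)."""
    if ic50 <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50}")
    factor = hill_factor(a, b, c)
    if mode == "log":
        return 10.0 ** (math.log10(ic50) / factor)
    if mode == "linear":
        return ic50 / factor
    raise ValueError(f"unknown conversion mode {mode!r}")


def assign_labels(dr: DoseResponse) -> ActivityLabelSet:
    """Assign binary/ternary/quaternary activity classes from a dose-response."""
    mi = dr.max_inhibition
    if mi is None:
        raise ValueError("max_inhibition is required for labeling")
    binary = "A" if mi >= 20 else "C"
    if mi > 50:
        if dr.ic50 is None:
            raise ValueError("max_inhibition > 50 but ic50 is unset")
        ternary = "A"
        quaternary = "A1" if dr.ic50 <= 10 else "A2"
    elif mi >= 20:
        ternary = quaternary = "B"
    else:
        ternary = quaternary = "C"
    return ActivityLabelSet(binary=binary, ternary=ternary, quaternary=quaternary)


@dataclass
class TableReadResult:
    """Rows parsed from an activity CSV plus collected row-level errors."""

    records: list[tuple[CompoundRecord, DoseResponse]]
    errors: list[str] = field(default_factory=list)
    extras: pd.DataFrame | None = None  # pass-through columns, indexed by id

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


_KNOWN_COLUMNS = ("id", "name", "smiles", "max_inhibition", "a", "b", "c", "ac50", "ic50", "source")


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or pd.isna(value):
        return None
    return float(value)


def read_activity_table(path) -> TableReadResult:
    """Read an activity CSV into ``(CompoundRecord, DoseResponse)`` pairs.

    The file must declare ``id``, ``smiles`` and either ``max_inhibition`` or
    the full curve parameters ``a, b, c``.  Rows with unparseable SMILES are
    skipped and reported in ``errors``; extra columns are preserved in
    ``extras``.
    """
    df = pd.read_csv(path, dtype={"id": str})
    cols = set(df.columns)
    if "id" not in cols or "smiles" not in cols:
        raise ValueError(f"missing mandatory column(s) in {path}: need 'id' and 'smiles'")
    if "max_inhibition" not in cols and not {"a", "b", "c"} <= cols:
        raise ValueError(
            f"missing mandatory column(s) in {path}: need 'max_inhibition' or curve parameters a, b, c"
        )
    records: list[tuple[CompoundRecord, DoseResponse]] = []
    errors: list[str] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        d = row._asdict()
        smiles = d.get("smiles")
        if not isinstance(smiles, str) or Chem.MolFromSmiles(smiles) is None:
            errors.append(f"row {row_no} (id={d.get('id')}): unparseable SMILES {smiles!r}")
            continue
        a = _opt_float(d.get("a"))
        max_inh = _opt_float(d.get("max_inhibition"))
        if max_inh is None and a is not None:
            max_inh = 100.0 - a
        name = d.get("name")
        source = d.get("source")
        rec = CompoundRecord(
            id=str(d["id"]),
            smiles=smiles,
            name=None if pd.isna(name) else str(name) if name is not None else None,
            source=(str(source) if source is not None and not pd.isna(source) else f"row {row_no}"),
        )
        dr = DoseResponse(
            a_min_response=a,
            b_max_response=_opt_float(d.get("b")),
            c_slope=_opt_float(d.get("c")),
            ac50=_opt_float(d.get("ac50")),
            max_inhibition=max_inh,
            ic50=_opt_float(d.get("ic50")),
        )
        records.append((rec, dr))
    extra_cols = [c for c in df.columns if c not in _KNOWN_COLUMNS]
    extras = None
    if extra_cols:
        extras = df.set_index(df["id"].astype(str))[extra_cols]
    return TableReadResult(records=records, errors=errors, extras=extras)


def deduplicate(
    records: Sequence[tuple[CompoundRecord, DoseResponse]],
) -> tuple[list[tuple[CompoundRecord, DoseResponse]], int]:
    """Collapse records sharing a canonical structure.

    Among duplicates the record with the most complete curve data is kept;
    ties are broken by lowest AC50, then first occurrence.  Returns the kept
    records (original order of their first occurrence) and the removal count.
    """
    best: dict[str, tuple[int, tuple]] = {}  # key -> (first position, (rec, dr))
    rank: dict[str, tuple] = {}
    for pos, (rec, dr) in enumerate(records):
        key = _canonical(rec.smiles)
        ac50 = dr.ac50 if dr.ac50 is not None else math.inf
        # higher completeness wins, then lower ac50, then earlier position
        score = (-dr.completeness(), ac50, pos)
        if key not in best or score < rank[key]:
            first = best[key][0] if key in best else pos
            best[key] = (first, (rec, dr))
            rank[key] = score
        # keep the earliest position as the output slot even if a later record wins
    kept = [pair for _, pair in sorted(best.values(), key=lambda t: t[0])]
    return kept, len(records) - len(kept)


@dataclass
class CurationLog:
    """What curation removed or failed to convert, row by row."""

    parse_errors: list[str] = field(default_factory=list)
    mixtures: list[str] = field(default_factory=list)
    inorganic: list[str] = field(default_factory=list)
    desalted: list[str] = field(default_factory=list)
    n_duplicates_removed: int = 0
    conversion_errors: list[str] = field(default_factory=list)

    def summary(self) -> str:
        return (
            f"parse errors: {len(self.parse_errors)}; mixtures removed: {len(self.mixtures)}; "
            f"inorganic removed: {len(self.inorganic)}; salts stripped: {len(self.desalted)}; "
            f"duplicates removed: {self.n_duplicates_removed}; "
            f"label/conversion errors: {len(self.conversion_errors)}"
        )


def curate_table(path, mode: str = "log") -> tuple[pd.DataFrame, CurationLog]:
    """Run the full curation pipeline on an activity CSV.

    Returns a curated table with columns ``id, name, smiles, max_inhibition,
    a, b, c, ac50, ic50, ic50_converted, conversion_mode, binary, ternary,
    quaternary`` (plus pass-through columns) and a :class:`CurationLog`.
    ``ic50`` in the output is the working IC50 (reported value if present,
    otherwise the converted one); ``ic50_converted`` holds the conversion
    result whenever it was computed.
    """
    read = read_activity_table(path)
    log = CurationLog(parse_errors=list(read.errors))

    cleaned: list[tuple[CompoundRecord, DoseResponse]] = []
    for rec, dr in read.records:
        try:
            parent = strip_salts_and_mixtures(rec.smiles)
        except MixtureError:
            log.mixtures.append(rec.id)
            continue
        except CurationError:
            log.inorganic.append(rec.id)
            continue
        if parent != _canonical(rec.smiles):
            log.desalted.append(rec.id)
        cleaned.append((CompoundRecord(rec.id, parent, rec.name, rec.source), dr))

    deduped, n_removed = deduplicate(cleaned)
    log.n_duplicates_removed = n_removed

    rows = []
    for rec, dr in deduped:
        ic50_converted = None
        ic50 = dr.ic50
        if dr.max_inhibition is not None and dr.max_inhibition > 50:
            if (
                dr.ac50 is not None
                and dr.a_min_response is not None
                and dr.b_max_response is not None
                and dr.c_slope is not None
            ):
                try:
                    ic50_converted = convert_ac50_to_ic50(
                        dr.ac50, dr.a_min_response, dr.b_max_response, dr.c_slope, mode=mode
                    )
                except (NotConvertibleError, ValueError) as exc:
                    log.conversion_errors.append(f"{rec.id}: {exc}")
            if ic50 is None:
                ic50 = ic50_converted
        try:
            labels = assign_labels(
                DoseResponse(
                    a_min_response=dr.a_min_response,
                    b_max_response=dr.b_max_response,
                    c_slope=dr.c_slope,
                    ac50=dr.ac50,
                    max_inhibition=dr.max_inhibition,
                    ic50=ic50,
                )
            )
        except ValueError as exc:
            log.conversion_errors.append(f"{rec.id}: {exc}")
            continue
        rows.append(
            {
                "id": rec.id,
                "name": rec.name,
                "smiles": rec.smiles,
                "max_inhibition": dr.max_inhibition,
                "a": dr.a_min_response,
                "b": dr.b_max_response,
                "c": dr.c_slope,
                "ac50": dr.ac50,
                "ic50": ic50,
                "ic50_converted": ic50_converted,
                "conversion_mode": mode if ic50_converted is not None else None,
                "binary": labels.binary,
                "ternary": labels.ternary,
                "quaternary": labels.quaternary,
            }
        )
    df = pd.DataFrame(rows)
    if read.extras is not None and not df.empty:
        extras = read.extras.drop(columns=[c for c in read.extras.columns if c in df.columns])
        if len(extras.columns):
            df = df.merge(extras, left_on="id", right_index=True, how="left")
    return df, log
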