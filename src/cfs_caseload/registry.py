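"""Domain types for substances, products and authorised uses, plus table I/O.

The package links three tables: a per-substance hazard table (endpoint
values and classification labels), a product table (which active
substances each plant protection product contains), and a use table
(product, crop, pest rows describing authorised uses).  All three are
plain UTF-8 delimited text with a header row; multi-valued cells are
``;``-separated and an empty cell always means *absent*, never zero.

Use matching is exact-string on normalized labels: leading/trailing
whitespace stripped, internal whitespace runs collapsed, case-folded.
No synonym or broad-spectrum expansion is attempted, so counts of
distinct uses are well defined.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd

from .errors import (
    IntegrityError,
    InvalidUseError,
    ReferentialError,
    RowParseError,
    SchemaError,
    VocabularyError,
)

#: Controlled vocabulary of substance use categories: acaricides,
#: fungicides, herbicides, insecticides, plant growth regulators,
#: repellents, rodenticides, and a catch-all for the small remaining
#: groups (attractants, bactericides, molluscicides, nematicides, ...).
USE_CATEGORIES = frozenset({"AC", "FU", "HB", "IN", "PG", "RE", "RO", "OTHER"})

#: CLP-style hazard class vocabularies ("none" = not classified).
CMR_CLASSES = frozenset({"1A", "1B", "2", "none"})
STOT_RE_CLASSES = frozenset({"1", "2", "none"})

#: Keys accepted in the optional pre-assessed boolean block.
PREASSESSED_KEYS = ("P", "B", "T_aqua", "T_human", "c1", "c4", "c6", "c7")

HAZARD_COLUMNS = [
    "substance_id", "name_aliases", "use_categories", "is_biopesticide",
    "adi", "arfd", "aoel",
    "dt50_water", "dt50_sediment", "dt50_soil", "bcf",
    "noec_fish", "noec_daphnia", "noec_algae", "noec_other",
    "carc_class", "muta_class", "repro_existing", "repro_forthcoming",
    "stot_re", "nonactive_isomers",
    "pre_P", "pre_B", "pre_Taqua", "pre_Thuman",
    "pre_c1", "pre_c4", "pre_c6", "pre_c7",
]

_PRE_COLUMN_TO_KEY = {
    "pre_P": "P", "pre_B": "B", "pre_Taqua": "T_aqua", "pre_Thuman": "T_human",
    "pre_c1": "c1", "pre_c4": "c4", "pre_c6": "c6", "pre_c7": "c7",
}

PRODUCT_COLUMNS = ["product_id", "name", "substance_ids", "categories"]
USE_COLUMNS = ["product_id", "crop", "pest"]

_WS_RUN = re.compile(r"\s+")

_NUMERIC_FIELDS = (
    "adi", "arfd", "aoel",
    "dt50_water", "dt50_sediment", "dt50_soil", "bcf",
    "noec_fish", "noec_daphnia", "noec_algae", "noec_other",
)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True, order=True)
class UseKey:
    """An authorised use: a (crop, pest) pair on normalized labels.

    "Crop" includes other treatment objects (e.g. food storage rooms)
    and "pest" other treatment aims (e.g. growth regulation); the two
    roles are kept distinct even when the labels coincide.
    """

    crop: str
    pest: str


@dataclass(frozen=True)
class SubstanceRecord:
    """One approved active substance, counted per its legal entry."""

    substance_id: str
    aliases: frozenset = frozenset()
    use_categories: frozenset = frozenset()
    is_biopesticide: bool = False

    def __post_init__(self):
        bad = set(self.use_categories) - USE_CATEGORIES
        if bad:
            raise VocabularyError(
                f"substance {self.substance_id!r}: unknown use categories {sorted(bad)}"
            )


@dataclass(frozen=True)
class HazardProfile:
    """Per-substance hazard endpoints and classification labels.

    Numeric endpoints are ``None`` when no value is available; the
    criterion logic must distinguish "no data" from "below threshold",
    so absence is never imputed as zero.  ``preassessed`` optionally
    carries already-assessed booleans for P, B, T_aqua, T_human and the
    criteria c1/c4/c6/c7; when present they take precedence over the
    raw-value thresholds (configurable).
    """

    substance_id: str
    adi: Optional[float] = None          # mg/kg bw/day
    arfd: Optional[float] = None         # mg/kg bw/day
    aoel: Optional[float] = None         # mg/kg bw/day
    dt50_water: Optional[float] = None   # days
    dt50_sediment: Optional[float] = None
    dt50_soil: Optional[float] = None
    bcf: Optional[float] = None          # L/kg
    noec_fish: Optional[float] = None    # mg/L, chronic
    noec_daphnia: Optional[float] = None
    noec_algae: Optional[float] = None
    noec_other: Optional[float] = None
    carc_class: str = "none"
    muta_class: str = "none"
    repro_class_existing: str = "none"
    repro_class_forthcoming: str = "none"
    stot_re_class: str = "none"
    nonactive_isomer_flag: Optional[bool] = None
    preassessed: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        for name in _NUMERIC_FIELDS:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise VocabularyError(
                    f"substance {self.substance_id!r}: {name} must be >= 0, got {v}"
                )
        for name in ("carc_class", "muta_class",
                     "repro_class_existing", "repro_class_forthcoming"):
            v = getattr(self, name)
            if v not in CMR_CLASSES:
                raise VocabularyError(
                    f"substance {self.substance_id!r}: {name} {v!r} not in "
                    f"{sorted(CMR_CLASSES)}"
                )
        if self.stot_re_class not in STOT_RE_CLASSES:
            raise VocabularyError(
                f"substance {self.substance_id!r}: stot_re_class "
                f"{self.stot_re_class!r} not in {sorted(STOT_RE_CLASSES)}"
            )
        bad = set(self.preassessed) - set(PREASSESSED_KEYS)
        if bad:
            raise VocabularyError(
                f"substance {self.substance_id!r}: unknown preassessed keys {sorted(bad)}"
            )


@dataclass(frozen=True)
class Product:
    """A plant protection product and its active-substance composition."""

    product_id: str
    name: str
    substance_ids: frozenset
    product_categories: frozenset = frozenset()

    def __post_init__(self):
        if not self.substance_ids:
            raise IntegrityError(
                f"product {self.product_id!r} has an empty substance list"
            )


class Finding(NamedTuple):
    severity: str  # "error" | "warning"
    message: str


@dataclass
class Registry:
    """Products plus their authorised uses, with a use -> products index."""

    products: dict            # product_id -> Product
    authorisations: dict      # product_id -> frozenset[UseKey]

    def __post_init__(self):
        orphans = set(self.authorisations) - set(self.products)
        if orphans:
            raise ReferentialError(
                f"authorisations reference unknown products {sorted(orphans)}"
            )
        for pid in self.products:
            self.authorisations.setdefault(pid, frozenset())
        self._index = None

    @property
    def use_index(self) -> dict:
        """Exact inverse of ``authorisations``: UseKey -> set of product_id."""
        if self._index is None:
            idx: dict = {}
            for pid, uses in self.authorisations.items():
                for u in uses:
                    idx.setdefault(u, set()).add(pid)
            self._index = idx
        return self._index

    def uses_of(self, product_id: str) -> frozenset:
        return self.authorisations.get(product_id, frozenset())

    def all_uses(self) -> set:
        out: set = set()
        for uses in self.authorisations.values():
            out |= uses
        return out

    @property
    def n_distinct_uses(self) -> int:
        return len(self.all_uses())

    def crops(self) -> set:
        return {u.crop for u in self.all_uses()}

    def pests(self) -> set:
        return {u.pest for u in self.all_uses()}


# ---------------------------------------------------------------------------
# use normalization


def _normalize_label(raw: str, fieldname: str) -> str:
    label = _WS_RUN.sub(" ", str(raw).strip()).casefold()
    if not label:
        raise InvalidUseError(f"empty {fieldname} label after trimming")
    return label


def normalize_use(crop: str, pest: str) -> UseKey:
    """Normalize a raw (crop, pest) pair into a :class:`UseKey`.

    Normalization is whitespace trimming/collapsing plus case folding;
    it is idempotent and performs no semantic matching.
    """
    return UseKey(
        crop=_normalize_label(crop, "crop"),
        pest=_normalize_label(pest, "pest"),
    )


# ---------------------------------------------------------------------------
# parsing helpers


def _cell(value) -> Optional[str]:
    """Raw cell -> stripped string or None for an absent value."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    s = str(value).strip()
    return s if s else None


def _parse_float(value, column: str, row: int) -> Optional[float]:
    s = _cell(value)
    if s is None:
        return None
    try:
        return float(s)
    except ValueError:
        raise RowParseError(
            f"row {row}: cannot parse {column}={s!r} as a number"
        ) from None


def _parse_bool(value, column: str, row: int) -> Optional[bool]:
    s = _cell(value)
    if s is None:
        return None
    low = s.casefold()
    if low in ("true", "1", "yes", "y"):
        return True
    if low in ("false", "0", "no", "n"):
        return False
    raise RowParseError(f"row {row}: cannot parse {column}={s!r} as a boolean")


def _parse_class(value, column: str, row: int, vocab: frozenset) -> str:
    s = _cell(value)
    if s is None:
        return "none"
    if s not in vocab:
        raise VocabularyError(
            f"row {row}: {column}={s!r} not in {sorted(vocab)}"
        )
    return s


def _split_multi(value) -> list:
    s = _cell(value)
    if s is None:
        return []
    return [part.strip() for part in s.split(";") if part.strip()]


def _read_csv(path, delimiter: str, expected: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=True)
    unknown = set(df.columns) - set(expected)
    missing = set(expected) - set(df.columns)
    if unknown or missing:
        parts = []
        if unknown:
            parts.append(f"unknown columns {sorted(unknown)}")
        if missing:
            parts.append(f"missing columns {sorted(missing)}")
        raise SchemaError(f"{path}: " + "; ".join(parts))
    return df


# ---------------------------------------------------------------------------
# hazard table I/O


def read_hazard_table(path, delimiter: str = ","):
    """Read the hazard table into ``[(SubstanceRecord, HazardProfile), ...]``.

    Missing cells become absent values (``None``), never zeros.  Raises
    :class:`SchemaError` for a column mismatch, :class:`IntegrityError`
    for duplicate substance ids or alias collisions, and
    :class:`VocabularyError` / :class:`RowParseError` for bad cells.
    """
    df = _read_csv(path, delimiter, HAZARD_COLUMNS)
    pairs = []
    seen: set = set()
    for row, rec in enumerate(df.itertuples(index=False)):
        d = rec._asdict()
        sid = _cell(d["substance_id"])
        if sid is None:
            raise RowParseError(f"row {row}: empty substance_id")
        if sid in seen:
            raise IntegrityError(f"duplicate substance_id {sid!r}")
        seen.add(sid)

        cats = frozenset(_split_multi(d["use_categories"]))
        record = SubstanceRecord(
            substance_id=sid,
            aliases=frozenset(_split_multi(d["name_aliases"])),
            use_categories=cats,
            is_biopesticide=bool(_parse_bool(d["is_biopesticide"],
                                             "is_biopesticide", row)),
        )
        pre = {}
        for col, key in _PRE_COLUMN_TO_KEY.items():
            v = _parse_bool(d[col], col, row)
            if v is not None:
                pre[key] = v
        profile = HazardProfile(
            substance_id=sid,
            **{f: _parse_float(d[f], f, row) for f in _NUMERIC_FIELDS},
            carc_class=_parse_class(d["carc_class"], "carc_class", row, CMR_CLASSES),
            muta_class=_parse_class(d["muta_class"], "muta_class", row, CMR_CLASSES),
            repro_class_existing=_parse_class(
                d["repro_existing"], "repro_existing", row, CMR_CLASSES),
            repro_class_forthcoming=_parse_class(
                d["repro_forthcoming"], "repro_forthcoming", row, CMR_CLASSES),
            stot_re_class=_parse_class(d["stot_re"], "stot_re", row, STOT_RE_CLASSES),
            nonactive_isomer_flag=_parse_bool(d["nonactive_isomers"],
                                              "nonactive_isomers", row),
            preassessed=pre,
        )
        pairs.append((record, profile))

    _check_alias_disjointness(r for r, _ in pairs)
    return pairs


def _check_alias_disjointness(records: Iterable[SubstanceRecord]):
    owner: dict = {}
    for rec in records:
        for a in rec.aliases:
            if a in owner and owner[a] != rec.substance_id:
                raise IntegrityError(
                    f"alias {a!r} claimed by both {owner[a]!r} and "
                    f"{rec.substance_id!r}"
                )
            owner[a] = rec.substance_id


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_hazard_table(pairs, path, delimiter: str = ","):
    """Write substance/profile pairs back to the documented CSV dialect."""
    rows = []
    for rec, prof in pairs:
        d = {
            "substance_id": rec.substance_id,
            "name_aliases": ";".join(sorted(rec.aliases)),
            "use_categories": ";".join(sorted(rec.use_categories)),
            "is_biopesticide": _fmt(rec.is_biopesticide),
        }
        for f in _NUMERIC_FIELDS:
            d[f] = _fmt(getattr(prof, f))
        for col, attr in (("carc_class", "carc_class"),
                          ("muta_class", "muta_class"),
                          ("repro_existing", "repro_class_existing"),
                          ("repro_forthcoming", "repro_class_forthcoming"),
                          ("stot_re", "stot_re_class")):
            v = getattr(prof, attr)
            d[col] = "" if v == "none" else v
        d["nonactive_isomers"] = _fmt(prof.nonactive_isomer_flag)
        for col, key in _PRE_COLUMN_TO_KEY.items():
            d[col] = _fmt(prof.preassessed.get(key))
        rows.append(d)
    pd.DataFrame(rows, columns=HAZARD_COLUMNS).to_csv(
        path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# registry I/O


def read_registry(products_path, uses_path, delimiter: str = ",") -> Registry:
    """Read the product and use tables into a :class:`Registry`.

    Authorisation rows are deduplicated per (product, normalized use).
    Use rows naming a product absent from the product table raise
    :class:`ReferentialError`.
    """
    pdf = _read_csv(products_path, delimiter, PRODUCT_COLUMNS)
    products: dict = {}
    for row, rec in enumerate(pdf.itertuples(index=False)):
        d = rec._asdict()
        pid = _cell(d["product_id"])
        if pid is None:
            raise RowParseError(f"row {row}: empty product_id")
        if pid in products:
            raise IntegrityError(f"duplicate product_id {pid!r}")
        products[pid] = Product(
            product_id=pid,
            name=_cell(d["name"]) or pid,
            substance_ids=frozenset(_split_multi(d["substance_ids"])),
            product_categories=frozenset(_split_multi(d["categories"])),
        )

    udf = _read_csv(uses_path, delimiter, USE_COLUMNS)
    authorisations: dict = {pid: set() for pid in products}
    for row, rec in enumerate(udf.itertuples(index=False)):
        d = rec._asdict()
        pid = _cell(d["product_id"])
        if pid not in products:
            raise ReferentialError(
                f"use row {row}: unknown product_id {pid!r}"
            )
        authorisations[pid].add(normalize_use(d["crop"] or "", d["pest"] or ""))

    return Registry(
        products=products,
        authorisations={p: frozenset(u) for p, u in authorisations.items()},
    )


def write_registry(reg: Registry, products_path, uses_path,
                   delimiter: str = ","):
    """Write a registry to the product/use CSV dialect (sorted, stable)."""
    prows = []
    for pid in sorted(reg.products):
        p = reg.products[pid]
        prows.append({
            "product_id": p.product_id,
            "name": p.name,
            "substance_ids": ";".join(sorted(p.substance_ids)),
            "categories": ";".join(sorted(p.product_categories)),
        })
    pd.DataFrame(prows, columns=PRODUCT_COLUMNS).to_csv(
        products_path, sep=delimiter, index=False)

    urows = []
    for pid in sorted(reg.authorisations):
        for use in sorted(reg.authorisations[pid]):
            urows.append({"product_id": pid, "crop": use.crop, "pest": use.pest})
    pd.DataFrame(urows, columns=USE_COLUMNS).to_csv(
        uses_path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# validation and alias resolution


def build_alias_index(substances: Iterable[SubstanceRecord]) -> dict:
    """Map every substance_id and alias to its canonical substance_id."""
    _check_alias_disjointness(substances := list(substances))
    index: dict = {}
    for rec in substances:
        if rec.substance_id in index and index[rec.substance_id] != rec.substance_id:
            raise IntegrityError(
                f"substance_id {rec.substance_id!r} collides with an alias"
            )
        index[rec.substance_id] = rec.substance_id
        for a in rec.aliases:
            if a in index and index[a] != rec.substance_id:
                raise IntegrityError(
                    f"alias {a!r} collides with substance {index[a]!r}"
                )
            index[a] = rec.substance_id
    return index


def validate_registry(reg: Registry,
                      substances: Iterable[SubstanceRecord]) -> list:
    """Return findings (never raises, never mutates).

    Error findings: product substance references that resolve to no
    substance_id or alias.  Warning findings: products with zero
    authorised uses; an entirely empty registry.
    """
    findings = []
    index = build_alias_index(substances)
    if not reg.products:
        findings.append(Finding("warning", "registry contains no products"))
    for pid in sorted(reg.products):
        p = reg.products[pid]
        for ref in sorted(p.substance_ids):
            if ref not in index:
                findings.append(Finding(
                    "error",
                    f"product {pid!r}: substance reference {ref!r} does not "
                    f"resolve to any substance or alias",
                ))
        if not reg.uses_of(pid):
            findings.append(Finding(
                "warning", f"product {pid!r} has no authorised uses"))
    return findings


def canonicalize_registry(reg: Registry,
                          substances: Iterable[SubstanceRecord]) -> Registry:
    """Rewrite product substance references to canonical substance ids.

    Unresolved references raise :class:`ReferentialError` — they never
    silently create new substances.
    """
    index = build_alias_index(substances)
    products = {}
    for pid, p in reg.products.items():
        resolved = set()
        for ref in p.substance_ids:
            if ref not in index:
                raise ReferentialError(
                    f"product {pid!r}: unresolved substance reference {ref!r}"
                )
            resolved.add(index[ref])
        products[pid] = dataclasses.replace(
            p, substance_ids=frozenset(resolved))
    return Registry(products=products,
                    authorisations=dict(reg.authorisations))
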