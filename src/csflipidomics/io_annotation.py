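"""Feature-table containers, CSV/TSV IO, lipid shorthand parsing and class curation.

The central object is :class:`FeatureTable`: a compounds x samples intensity
matrix (pandas DataFrame, NaN = missing, never imputed) together with sample
metadata (role: control / case / qc, age, sex) and compound annotations
(parsed lipid shorthand, annotation confidence level, main class).

Lipid names follow the field's shorthand nomenclature: a class abbreviation
followed by total acyl carbons and double bonds ("PC 32:0"), optionally with
per-chain detail in parentheses ("PC (16:0/16:0)", "plasmenyl-PE 36:1
(18:0/18:1)").  Parsing is a total function: anything unrecognized comes back
as class "unclassified" with the raw name preserved.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig

log = logging.getLogger(__name__)

ROLE_CONTROL = "control"
ROLE_CASE = "case"
ROLE_QC = "qc"
ROLES = (ROLE_CONTROL, ROLE_CASE, ROLE_QC)

ANNOTATION_LEVELS = ("1", "2a", "2b", "3")

SMALL_GROUP = "small group collection"
UNCLASSIFIED = "unclassified"

#: Tokens counted as missing when reading numeric cells.
MISSING_TOKENS = {"", "na", "nan", "n/a", "none", "null", "missing"}


# ---------------------------------------------------------------------------
# Lipid shorthand parsing
# ---------------------------------------------------------------------------

#: Abbreviation -> canonical main-class name.  Longest registered prefix of a
#: raw name wins; users can extend via :func:`register_lipid_class`.
CLASS_REGISTRY: dict[str, str] = {
    # ether (plasmalogen) glycerophospholipids
    "plasmenyl-PC": "plasmenylphosphatidylcholine",
    "plasmenyl-PE": "plasmenylphosphatidylethanolamine",
    "plasmanyl-PC": "plasmanylphosphatidylcholine",
    "plasmanyl-PE": "plasmanylphosphatidylethanolamine",
    # lyso species before their parent classes (longest match also guards this)
    "LPC": "lysophosphatidylcholine",
    "LPE": "lysophosphatidylethanolamine",
    "LPA": "lysophosphatidic acid",
    "LPS": "lysophosphatidylserine",
    "LPI": "lysophosphatidylinositol",
    # diacyl glycerophospholipids
    "PC": "phosphatidylcholine",
    "PE": "phosphatidylethanolamine",
    "PA": "phosphatidic acid",
    "PS": "phosphatidylserine",
    "PI": "phosphatidylinositol",
    "PG": "phosphatidylglycerol",
    # sphingolipids
    "SM": "sphingomyelin",
    "Cer": "ceramide",
    "HexCer": "hexosylceramide",
    # glycerolipids
    "TG": "triacylglycerol",
    "DG": "diacylglycerol",
    "MG": "monoacylglycerol",
    # sterols, acyls, amides
    "CE": "cholesteryl ester",
    "FA": "fatty acid",
    "amide": "amide",
    "carnitine": "acylcarnitine",
}

#: Full class names also resolve to themselves (case-insensitive).
_CANONICAL_NAMES = {
    "phosphatidylcholine", "phosphatidylethanolamine", "phosphatidic acid",
    "phosphatidylserine", "phosphatidylinositol", "phosphatidylglycerol",
    "lysophosphatidylcholine", "lysophosphatidylethanolamine",
    "lysophosphatidic acid", "plasmenylphosphatidylcholine",
    "plasmenylphosphatidylethanolamine", "sphingomyelin", "ceramide",
    "triacylglycerol", "diacylglycerol", "monoacylglycerol",
    "cholesteryl ester", "fatty acid", "amide", "acylcarnitine",
}

#: Preferred abbreviation for rendering, derived from the registry
#: (first abbreviation registered for each canonical name wins).
_PREFERRED_ABBREV: dict[str, str] = {}
for _abbr, _canon in CLASS_REGISTRY.items():
    _PREFERRED_ABBREV.setdefault(_canon, _abbr)


def register_lipid_class(abbreviation: str, canonical_name: str) -> None:
    """Add a class abbreviation to the shorthand parser's registry."""
    CLASS_REGISTRY[abbreviation] = canonical_name
    _CANONICAL_NAMES.add(canonical_name.lower())
    _PREFERRED_ABBREV.setdefault(canonical_name, abbreviation)


_ISOTOPE_LABEL_RE = re.compile(r"\(d\d+\)")
_TOTAL_RE = re.compile(r"(?<![\d:])(\d{1,3}):(\d{1,2})(?![\d:])")
_CHAINS_RE = re.compile(r"\((\d{1,2}:\d{1,2}(?:/\d{1,2}:\d{1,2})+)\)")
_SINGLE_CHAIN_PAREN_RE = re.compile(r"\((\d{1,2}:\d{1,2})\)")
_CARBON_ONLY_RE = re.compile(r"\bC(\d{1,3})\b")


@dataclass
class LipidAnnotation:
    """A parsed lipid shorthand name plus curation metadata.

    ``total_carbons``/``total_double_bonds`` are None when the name carries no
    composition; ``chain_detail`` lists per-acyl (carbons, double_bonds) pairs
    when the name gives them, and always sums to the totals.
    """

    compound_id: str
    raw_name: str
    main_class: str = UNCLASSIFIED
    total_carbons: int | None = None
    total_double_bonds: int | None = None
    chain_detail: list[tuple[int, int]] | None = None
    annotation_level: str = "1"
    is_biological: bool = True

    def __post_init__(self) -> None:
        if self.annotation_level not in ANNOTATION_LEVELS:
            raise ValueError(
                f"annotation_level must be one of {ANNOTATION_LEVELS}, "
                f"got {self.annotation_level!r}"
            )
        if (
            self.total_carbons is not None
            and self.total_double_bonds is not None
            and not (self.total_carbons >= self.total_double_bonds >= 0)
        ):
            raise ValueError(
                f"{self.raw_name!r}: need total_carbons >= total_double_bonds >= 0, "
                f"got {self.total_carbons}:{self.total_double_bonds}"
            )
        if self.chain_detail is not None:
            c = sum(ch[0] for ch in self.chain_detail)
            d = sum(ch[1] for ch in self.chain_detail)
            if self.total_carbons is None:
                self.total_carbons = c
                self.total_double_bonds = d
            elif (c, d) != (self.total_carbons, self.total_double_bonds):
                raise ValueError(
                    f"{self.raw_name!r}: chains sum to {c}:{d}, totals say "
                    f"{self.total_carbons}:{self.total_double_bonds}"
                )

    def shorthand(self) -> str:
        """Render the annotation back into canonical shorthand.

        ``parse_lipid_name`` is idempotent on this output.
        """
        cls = _PREFERRED_ABBREV.get(self.main_class, self.main_class)
        parts = [cls]
        if self.total_carbons is not None and self.total_double_bonds is not None:
            parts.append(f"{self.total_carbons}:{self.total_double_bonds}")
        elif self.total_carbons is not None:
            parts.append(f"C{self.total_carbons}")
        if self.chain_detail:
            parts.append("(" + "/".join(f"{c}:{d}" for c, d in self.chain_detail) + ")")
        return " ".join(parts)


def _match_class(name: str) -> tuple[str, str] | None:
    """Longest registered prefix match; returns (canonical class, matched token)."""
    best: tuple[str, str] | None = None
    stripped = name.strip()
    low = stripped.lower()
    for abbr, canonical in CLASS_REGISTRY.items():
        if low.startswith(abbr.lower()):
            # token boundary: next char must not be a letter (PC vs PCX)
            nxt = stripped[len(abbr) : len(abbr) + 1]
            if nxt.isalpha():
                continue
            if best is None or len(abbr) > len(best[1]):
                best = (canonical, stripped[: len(abbr)])
    for canonical in _CANONICAL_NAMES:
        if low.startswith(canonical):
            if best is None or len(canonical) > len(best[1]):
                best = (canonical if canonical in _PREFERRED_ABBREV else canonical,
                        stripped[: len(canonical)])
    return best


def parse_lipid_name(raw_name: str, compound_id: str | None = None) -> LipidAnnotation:
    """Parse a lipid shorthand name; total function, never raises on content.

    Recognizes "CLASS CC:DB", "CLASS (c1:d1/c2:d2/...)", "CLASS CC:DB
    (c1:d1/...)" and carbon-only forms like "amide C18".  Isotope-labelled
    internal standards (a "(dN)" tag, e.g. "15:0-18:1(d7)PC") parse with
    ``is_biological=False`` — they are QC spike-ins, not analytes.
    Unrecognized names come back as class "unclassified".
    """
    if not isinstance(raw_name, str) or not raw_name.strip():
        raise ValueError("raw_name must be a non-empty string")
    cid = compound_id if compound_id is not None else raw_name
    name = raw_name.strip()

    is_standard = bool(_ISOTOPE_LABEL_RE.search(name))
    work = _ISOTOPE_LABEL_RE.sub("", name) if is_standard else name

    matched = _match_class(work)
    main_class = UNCLASSIFIED
    rest = work
    if matched is None and is_standard:
        # internal standards often carry the class token at the END
        # ("15:0-18:1(d7)PC"): retry on the trailing alphabetic token
        m = re.search(r"([A-Za-z-]+)\s*$", work)
        if m:
            matched = _match_class(m.group(1))
            if matched:
                rest = ""  # leading chain spec belongs to the standard mix
    if matched is not None:
        main_class = matched[0]
        if rest is work:
            rest = work[len(matched[1]):]

    chains: list[tuple[int, int]] | None = None
    m = _CHAINS_RE.search(rest)
    if m is None:
        m = _SINGLE_CHAIN_PAREN_RE.search(rest)
    if m is not None:
        chains = [tuple(int(v) for v in ch.split(":")) for ch in m.group(1).split("/")]
        rest = rest[: m.start()] + rest[m.end():]

    carbons = bonds = None
    m = _TOTAL_RE.search(rest)
    if m is not None:
        carbons, bonds = int(m.group(1)), int(m.group(2))
    else:
        m = _CARBON_ONLY_RE.search(rest)
        if m is not None:
            carbons = int(m.group(1))

    if main_class == UNCLASSIFIED:
        log.debug("unrecognized lipid name %r", raw_name)
        return LipidAnnotation(cid, raw_name, UNCLASSIFIED, is_biological=False)

    try:
        return LipidAnnotation(
            compound_id=cid,
            raw_name=raw_name,
            main_class=main_class,
            total_carbons=carbons,
            total_double_bonds=bonds,
            chain_detail=chains,
            is_biological=not is_standard,
        )
    except ValueError as exc:  # inconsistent composition: degrade, never raise
        log.warning("lipid name %r failed validation (%s); kept unclassified", raw_name, exc)
        return LipidAnnotation(cid, raw_name, UNCLASSIFIED, is_biological=False)


# ---------------------------------------------------------------------------
# FeatureTable
# ---------------------------------------------------------------------------

SAMPLE_COLUMNS = ("role", "age", "sex")
COMPOUND_COLUMNS = (
    "name", "main_class", "annotation_level", "is_biological",
    "total_carbons", "total_double_bonds",
)


@dataclass
class FeatureTable:
    """Compounds x samples intensity matrix with sample and compound metadata.

    ``intensities``: DataFrame indexed by compound_id with sample_id columns;
    NaN marks a missing measurement (distinct from zero).  ``samples`` is
    indexed by sample_id with columns role/age/sex; ``compounds`` is indexed
    by compound_id with the annotation columns.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    compounds: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        mat = self.intensities
        if mat.index.has_duplicates:
            dups = mat.index[mat.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate compound ids in matrix: {dups}")
        if mat.columns.has_duplicates:
            dups = mat.columns[mat.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids in matrix: {dups}")
        if self.samples.index.has_duplicates:
            raise ValueError("duplicate sample ids in sample metadata")
        if self.compounds.index.has_duplicates:
            raise ValueError("duplicate compound ids in compound metadata")

        missing_s = [s for s in mat.columns if s not in self.samples.index]
        if missing_s:
            raise ValueError(f"matrix samples absent from sample metadata: {missing_s}")
        extra_s = [s for s in self.samples.index if s not in mat.columns]
        if extra_s:
            raise ValueError(f"metadata samples absent from matrix: {extra_s}")
        missing_c = [c for c in mat.index if c not in self.compounds.index]
        if missing_c:
            raise ValueError(f"matrix compounds absent from compound metadata: {missing_c}")
        extra_c = [c for c in self.compounds.index if c not in mat.index]
        if extra_c:
            raise ValueError(f"metadata compounds absent from matrix: {extra_c}")

        bad_roles = set(self.samples["role"]) - set(ROLES)
        if bad_roles:
            raise ValueError(f"unknown sample roles: {sorted(bad_roles)}")
        ages = pd.to_numeric(self.samples.get("age"), errors="coerce")
        if (ages.dropna() < 0).any():
            raise ValueError("negative ages in sample metadata")

        vals = mat.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("intensities must be non-negative")

        # align metadata ordering with the matrix
        self.samples = self.samples.loc[mat.columns]
        self.compounds = self.compounds.loc[mat.index]

    # -- convenience --------------------------------------------------------
    @property
    def compound_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def n_compounds(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def sample_ids(self, role: str | None = None) -> list[str]:
        if role is None:
            return list(self.samples.index)
        return list(self.samples.index[self.samples["role"] == role])

    @property
    def control_ids(self) -> list[str]:
        return self.sample_ids(ROLE_CONTROL)

    @property
    def case_ids(self) -> list[str]:
        return self.sample_ids(ROLE_CASE)

    @property
    def qc_ids(self) -> list[str]:
        return self.sample_ids(ROLE_QC)

    @property
    def biological_ids(self) -> list[str]:
        return [s for s in self.samples.index if self.samples.at[s, "role"] != ROLE_QC]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(), self.samples.copy(), self.compounds.copy()
        )

    def subset_compounds(self, compound_ids: Sequence[str]) -> "FeatureTable":
        ids = [c for c in self.compound_ids if c in set(compound_ids)]
        return FeatureTable(
            self.intensities.loc[ids], self.samples.copy(), self.compounds.loc[ids]
        )

    def drop_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        drop = set(sample_ids)
        keep = [s for s in self.samples.index if s not in drop]
        return FeatureTable(
            self.intensities[keep], self.samples.loc[keep], self.compounds.copy()
        )


def _sep_for(path: str | Path) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab", ".txt")) else ","


def read_feature_table(
    intensity_path: str | Path,
    sample_meta_path: str | Path,
    compound_meta_path: str | Path,
) -> FeatureTable:
    """Read and validate the three input tables (CSV or TSV by extension).

    The intensity matrix has compound ids in the first column and sample ids
    as remaining headers.  Cells that do not parse as numbers become missing
    values (NaN, distinct from zero) with a logged count.  Mismatched or
    duplicate ids raise with the offending names.
    """
    raw = pd.read_csv(intensity_path, sep=_sep_for(intensity_path), dtype=str)
    raw = raw.set_index(raw.columns[0])
    raw.index.name = "compound_id"

    def _cell(v: object) -> float:
        # float() is correctly rounded, unlike the pandas fast parser
        try:
            return float(v)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            return np.nan

    mat = raw.map(_cell).astype(float)

    stripped = raw.apply(lambda col: col.str.strip().str.lower())
    expected_missing = raw.isna() | stripped.isin(MISSING_TOKENS)
    unparseable = int((mat.isna() & ~expected_missing).sum().sum())
    if unparseable:
        log.warning("%d non-numeric cells coerced to missing in %s", unparseable, intensity_path)

    samples = pd.read_csv(sample_meta_path, sep=_sep_for(sample_meta_path))
    samples = samples.set_index("sample_id")
    for col in SAMPLE_COLUMNS:
        if col not in samples.columns:
            samples[col] = np.nan
    samples["age"] = pd.to_numeric(samples["age"], errors="coerce")

    cmeta = pd.read_csv(compound_meta_path, sep=_sep_for(compound_meta_path))
    cmeta = cmeta.set_index("compound_id")
    if "name" not in cmeta.columns:
        raise ValueError("compound metadata needs a 'name' column")
    if "annotation_level" not in cmeta.columns:
        cmeta["annotation_level"] = "1"
    cmeta["annotation_level"] = cmeta["annotation_level"].astype(str)

    # fill class / composition columns from the shorthand parser where absent
    parsed = {cid: parse_lipid_name(str(nm), cid) for cid, nm in cmeta["name"].items()}
    if "main_class" not in cmeta.columns:
        cmeta["main_class"] = [parsed[c].main_class for c in cmeta.index]
    else:
        blank = cmeta["main_class"].isna() | (cmeta["main_class"].astype(str).str.strip() == "")
        cmeta.loc[blank, "main_class"] = [parsed[c].main_class for c in cmeta.index[blank]]
    if "is_biological" not in cmeta.columns:
        cmeta["is_biological"] = [parsed[c].is_biological for c in cmeta.index]
    else:
        cmeta["is_biological"] = cmeta["is_biological"].astype(bool)
    for col, attr in (("total_carbons", "total_carbons"),
                      ("total_double_bonds", "total_double_bonds")):
        if col not in cmeta.columns:
            cmeta[col] = [getattr(parsed[c], attr) for c in cmeta.index]

    return FeatureTable(mat, samples, cmeta)


def write_feature_table(table: FeatureTable, out_dir: str | Path,
                        prefix: str = "feature_table") -> dict[str, Path]:
    """Write the three CSVs; a read of the output round-trips the table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "intensities": out / f"{prefix}_intensities.csv",
        "samples": out / f"{prefix}_samples.csv",
        "compounds": out / f"{prefix}_compounds.csv",
    }
    mat = table.intensities.copy()
    mat.index.name = "compound_id"
    # repr-precision floats so the round trip is exact
    mat.to_csv(paths["intensities"], float_format="%.17g")
    samples = table.samples.copy()
    samples.index.name = "sample_id"
    samples.to_csv(paths["samples"])
    compounds = table.compounds.copy()
    compounds.index.name = "compound_id"
    compounds.to_csv(paths["compounds"])
    return paths


# ---------------------------------------------------------------------------
# Class curation
# ---------------------------------------------------------------------------

@dataclass
class GroupScheme:
    """Mapping of main lipid classes to analysis groups after small-class merge.

    Classes with fewer than ``min_group_size`` members among the retained
    (biological, classified, level 1/2) lipids are pooled into the
    "small group collection"; every retained compound belongs to exactly one
    group.
    """

    group_of: dict[str, str]
    small_group_members: set[str]
    min_group_size: int
    retained_compounds: list[str] = field(default_factory=list)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.group_of.values():
            seen.setdefault(g, None)
        return list(seen)

    def assign(self, compounds: pd.DataFrame) -> pd.Series:
        """Series compound_id -> group for the retained compounds present."""
        retained = set(self.retained_compounds)
        ids = [c for c in compounds.index if c in retained]
        sub = compounds.loc[ids]
        return sub["main_class"].map(self.group_of).rename("group")


def _as_compound_frame(
    compounds: pd.DataFrame | Sequence[LipidAnnotation],
) -> pd.DataFrame:
    if isinstance(compounds, pd.DataFrame):
        return compounds
    rows = {
        a.compound_id: {
            "name": a.raw_name,
            "main_class": a.main_class,
            "annotation_level": a.annotation_level,
            "is_biological": a.is_biological,
            "total_carbons": a.total_carbons,
            "total_double_bonds": a.total_double_bonds,
        }
        for a in compounds
    }
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "compound_id"
    return frame


def curate_classes(
    compounds: pd.DataFrame | Sequence[LipidAnnotation],
    config: PipelineConfig | None = None,
) -> GroupScheme:
    """Drop non-biological / unclassified / level-3 compounds and merge small classes.

    Exclusions: ``is_biological == False`` (drugs, sugars, internal standards,
    "others"), class "unclassified", and annotation level 3.  Among the
    retained lipids, every main class with fewer than ``min_group_size``
    members is pooled into the "small group collection"; the rest keep their
    class as their group.
    """
    config = config or PipelineConfig()
    frame = _as_compound_frame(compounds)
    if frame.empty:
        raise ValueError("no compounds to curate")

    level = frame["annotation_level"].astype(str)
    keep = (
        frame["is_biological"].astype(bool)
        & (frame["main_class"] != UNCLASSIFIED)
        & frame["main_class"].notna()
        & (level != "3")
    )
    dropped = int((~keep).sum())
    if dropped:
        log.info("curation dropped %d non-biological/unclassified/level-3 compounds", dropped)
    retained = frame[keep]
    if retained.empty:
        raise ValueError("curation retained no compounds")

    counts = retained["main_class"].value_counts()
    small = set(counts.index[counts < config.min_group_size])
    group_of = {
        cls: (SMALL_GROUP if cls in small else cls) for cls in counts.index
    }
    if small:
        log.info(
            "merged %d classes (<%d members) into '%s'",
            len(small), config.min_group_size, SMALL_GROUP,
        )
    return GroupScheme(
        group_of=group_of,
        small_group_members=small,
        min_group_size=config.min_group_size,
        retained_compounds=list(retained.index),
    )
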