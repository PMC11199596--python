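"""Domain types and table I/O for immuno-MRM panel characterization.

The package works on three kinds of tables:

* **panel definition** — one row per target peptide (gene symbol, sequence,
  extended heavy-standard sequence, antibody and portal identifiers);
* **MRM parameters** — one row per monitored transition (precursor/fragment
  m/z, charges, collision energy, isotope label);
* **transition report** — one row per integrated transition per replicate per
  isotope label, as exported from Skyline (peak area, background, retention
  time, sample annotations).

Readers accept CSV or XLSX, resolve Skyline header dialects through a
case-insensitive alias map, and return either typed records or tidy pandas
DataFrames with normalized column names. All downstream statistics are
invariant to input row order.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("iomrm")

VALID_AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

#: Values treated as missing in any input table (mixed provenance of
#: deposited records: Excel emits "#N/A", R emits "NA", CSV emits "").
MISSING_MARKERS = {"#N/A", "N/A", "NA", "", "nan", "NaN", "#VALUE!"}

LIGHT = "light"
HEAVY = "heavy"

_LABEL_ALIASES = {
    "light": LIGHT,
    "l": LIGHT,
    "endogenous": LIGHT,
    "heavy": HEAVY,
    "h": HEAVY,
    "heavy (r)": HEAVY,
    "heavy (k)": HEAVY,
}


class SchemaError(ValueError):
    """A mandatory column could not be resolved in an input table."""


class ValidationError(ValueError):
    """Row-level content failed validation; offending rows are listed."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelTarget:
    """One target analyte of a panel: a proteotypic surrogate peptide."""

    gene_symbol: str
    sequence: str
    peptide_id: str = ""
    modification: str | None = None
    extended_heavy_sequence: str | None = None
    antibody_id: str | None = None
    assay_portal_id: str | None = None
    antibody_portal_id: str | None = None

    def __post_init__(self) -> None:
        if not self.peptide_id:
            object.__setattr__(self, "peptide_id", default_peptide_id(self.gene_symbol, self.sequence, self.modification))
        bad = set(self.sequence) - VALID_AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"peptide {self.peptide_id}: non-standard residues {sorted(bad)}"
            )
        if self.sequence[-1] not in "KR":
            # Tolerated (C-terminal protein peptides, atypical targets) but
            # worth flagging: the panel is built on fully tryptic peptides.
            logger.warning(
                "peptide %s does not end in K/R (non-tryptic C-terminus)",
                self.peptide_id,
            )
        if self.extended_heavy_sequence:
            stripped = re.sub(r"[^A-Z]", "", self.extended_heavy_sequence.upper())
            if self.sequence not in stripped:
                raise ValidationError(
                    f"peptide {self.peptide_id}: extended heavy sequence does not "
                    f"contain the target sequence"
                )


def default_peptide_id(gene_symbol: str, sequence: str, modification: str | None = None) -> str:
    """Panel naming convention: gene symbol + first four residues.

    A modified form carries a modification tag so it stays distinct from the
    unmodified peptide, e.g. ``MUTYH_MGQQox`` for the Met-oxidized form of
    ``MUTYH_MGQQ``.
    """
    tag = f"{gene_symbol}_{sequence[:4]}"
    if modification:
        mod = re.sub(r"[^A-Za-z0-9]", "", modification)
        tag = f"{tag}{mod}" if mod else tag
    return tag


@dataclass(frozen=True)
class MrmTransition:
    """One monitored precursor/fragment pair with acquisition parameters."""

    peptide_id: str
    precursor_mz: float
    precursor_charge: int
    fragment_name: str
    fragment_mz: float
    fragment_charge: int
    collision_energy: float
    label: str

    def __post_init__(self) -> None:
        if self.precursor_mz <= 0 or self.fragment_mz <= 0:
            raise ValidationError(f"{self.peptide_id}/{self.fragment_name}: m/z must be > 0")
        if self.precursor_charge < 1 or self.fragment_charge < 1:
            raise ValidationError(f"{self.peptide_id}/{self.fragment_name}: charge must be >= 1")
        if self.label not in (LIGHT, HEAVY):
            raise ValidationError(f"{self.peptide_id}: unknown label {self.label!r}")


@dataclass(frozen=True)
class TransitionRecord:
    """One integrated transition measurement from an exported report."""

    peptide_id: str
    label: str
    replicate_id: str
    fragment_name: str
    area: float
    background: float
    retention_time: float | None = None
    sample_annotations: Mapping[str, object] = field(default_factory=dict)


@dataclass
class PanelDefinition:
    """A named panel: its targets and (optionally) its MRM transitions."""

    targets: list[PanelTarget]
    transitions: list[MrmTransition] = field(default_factory=list)
    panel_name: str = "custom"

    def __post_init__(self) -> None:
        ids = [t.peptide_id for t in self.targets]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate peptide_ids in panel: {sorted(dupes)}")
        known = set(ids)
        orphans = {t.peptide_id for t in self.transitions} - known
        if orphans:
            raise ValidationError(
                f"transitions reference peptides absent from the panel: {sorted(orphans)}"
            )

    @property
    def peptide_ids(self) -> list[str]:
        return [t.peptide_id for t in self.targets]

    def __len__(self) -> int:
        return len(self.targets)


# ---------------------------------------------------------------------------
# Header alias resolution
# ---------------------------------------------------------------------------

# Skyline report templates vary; every logical column is matched
# case-insensitively against this alias list.
PANEL_ALIASES: dict[str, tuple[str, ...]] = {
    "gene_symbol": ("gene_symbol", "gene", "gene symbol", "protein", "protein name"),
    "sequence": ("sequence", "peptide", "peptide sequence", "target peptide sequence", "peptide modified sequence"),
    "peptide_id": ("peptide_id", "peptide id", "analyte", "assay id"),
    "modification": ("modification", "mod", "ptm"),
    "extended_heavy_sequence": ("extended_heavy_sequence", "extended sequence", "extended peptide sequence", "heavy extended sequence"),
    "antibody_id": ("antibody_id", "antibody", "antibody id", "mab id"),
    "assay_portal_id": ("assay_portal_id", "assay portal id", "assay portal"),
    "antibody_portal_id": ("antibody_portal_id", "antibody portal id", "antibody portal"),
}

MRM_ALIASES: dict[str, tuple[str, ...]] = {
    "peptide_id": ("peptide_id", "peptide id", "peptide", "analyte"),
    "precursor_mz": ("precursor_mz", "precursor mz", "precursor m/z", "q1", "q1 m/z"),
    "precursor_charge": ("precursor_charge", "precursor charge", "charge"),
    "fragment_name": ("fragment_name", "fragment", "fragment ion", "product ion"),
    "fragment_mz": ("fragment_mz", "fragment mz", "product m/z", "q3", "q3 m/z"),
    "fragment_charge": ("fragment_charge", "fragment charge", "product charge"),
    "collision_energy": ("collision_energy", "collision energy", "ce"),
    "label": ("label", "isotope label", "isotope label type"),
}

TRANSITION_ALIASES: dict[str, tuple[str, ...]] = {
    "peptide_id": ("peptide_id", "peptide id", "peptide", "peptide modified sequence", "analyte"),
    "label": ("label", "isotope label", "isotope label type"),
    "replicate_id": ("replicate_id", "replicate", "replicate name", "file name"),
    "fragment_name": ("fragment_name", "fragment", "fragment ion", "product ion"),
    "area": ("area", "total area", "peak area", "area fragment"),
    "background": ("background", "total background", "background fragment"),
    "retention_time": ("retention_time", "retention time", "rt", "best retention time"),
}

#: Sample-annotation columns the pipeline recognizes; anything else present
#: in a report is carried along untouched.
KNOWN_ANNOTATIONS = (
    "matrix", "day", "spike_level", "spike_fmol", "heavy_spike_fmol",
    "condition", "panel", "position", "sample_id", "site", "design",
)


def _normalize_header(name: str) -> str:
    return re.sub(r"\s+", " ", str(name).strip().lower())


def resolve_columns(
    columns: Sequence[str],
    aliases: Mapping[str, tuple[str, ...]],
    required: Iterable[str],
) -> dict[str, str]:
    """Map logical field names to actual table columns via the alias table.

    Raises :class:`SchemaError` naming the first unresolvable required field.
    """
    normalized = {_normalize_header(c): c for c in columns}
    out: dict[str, str] = {}
    for logical, names in aliases.items():
        for candidate in names:
            if candidate in normalized:
                out[logical] = normalized[candidate]
                break
    missing = [f for f in required if f not in out]
    if missing:
        raise SchemaError(
            f"could not resolve mandatory column(s) {missing}; "
            f"available columns: {list(columns)}"
        )
    return out


def _read_table(path: str | Path, sheet: str | int | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        try:
            return pd.read_excel(path, sheet_name=sheet if sheet is not None else 0)
        except ValueError:
            # named sheet absent: positional fallback to the first sheet
            return pd.read_excel(path, sheet_name=0)
    return pd.read_csv(path, skip_blank_lines=True)


def _clean_missing(df: pd.DataFrame) -> pd.DataFrame:
    return df.replace(list(MISSING_MARKERS), np.nan)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_panel_table(
    path: str | Path,
    format_hint: str | None = None,
    panel_name: str = "custom",
    sheet: str | int | None = None,
) -> PanelDefinition:
    """Read a panel definition table (CSV/XLSX) into a validated panel.

    ``format_hint`` may be ``"csv"`` or ``"xlsx"``; by default the suffix
    decides. Peptide ids are taken from the table when present, otherwise
    derived as ``GENE_XXXX`` from the gene symbol and first four residues.
    """
    df = _clean_missing(_read_table(path, sheet=sheet))
    if df.empty:
        logger.warning("panel table %s is empty", path)
        return PanelDefinition(targets=[], panel_name=panel_name)
    cols = resolve_columns(df.columns, PANEL_ALIASES, required=("gene_symbol", "sequence"))
    targets = []
    for _, row in df.iterrows():
        def get(logical: str) -> str | None:
            col = cols.get(logical)
            if col is None:
                return None
            val = row[col]
            return None if pd.isna(val) else str(val).strip()

        seq = get("sequence")
        gene = get("gene_symbol")
        if not seq or not gene:
            continue
        targets.append(
            PanelTarget(
                gene_symbol=gene,
                sequence=re.sub(r"\[.*?\]", "", seq).upper(),
                peptide_id=get("peptide_id") or "",
                modification=get("modification"),
                extended_heavy_sequence=get("extended_heavy_sequence"),
                antibody_id=get("antibody_id"),
                assay_portal_id=get("assay_portal_id"),
                antibody_portal_id=get("antibody_portal_id"),
            )
        )
    return PanelDefinition(targets=targets, panel_name=panel_name)


def read_mrm_table(path: str | Path, sheet: str | int | None = None) -> list[MrmTransition]:
    """Read an MRM parameter table (one row per transition)."""
    df = _clean_missing(_read_table(path, sheet=sheet))
    required = ("peptide_id", "precursor_mz", "precursor_charge", "fragment_name", "fragment_mz")
    cols = resolve_columns(df.columns, MRM_ALIASES, required=required)
    out = []
    for _, row in df.iterrows():
        label = str(row[cols["label"]]).strip().lower() if "label" in cols else LIGHT
        out.append(
            MrmTransition(
                peptide_id=str(row[cols["peptide_id"]]),
                precursor_mz=float(row[cols["precursor_mz"]]),
                precursor_charge=int(row[cols["precursor_charge"]]),
                fragment_name=str(row[cols["fragment_name"]]),
                fragment_mz=float(row[cols["fragment_mz"]]),
                fragment_charge=int(row[cols["fragment_charge"]]) if "fragment_charge" in cols else 1,
                collision_energy=float(row[cols["collision_energy"]]) if "collision_energy" in cols else 0.0,
                label=_LABEL_ALIASES.get(label, label),
            )
        )
    return out


def read_transition_report(path: str | Path, sheet: str | int | None = None) -> pd.DataFrame:
    """Read an exported transition report into the tidy transition table.

    Returns a DataFrame with the normalized columns ``peptide_id``, ``label``,
    ``replicate_id``, ``fragment_name``, ``area``, ``background``,
    ``retention_time`` plus any sample-annotation columns present. Rows with
    negative or unparseable area/background raise :class:`ValidationError`
    listing the offending row numbers.
    """
    raw = _clean_missing(_read_table(path, sheet=sheet))
    return normalize_transition_frame(raw)


def normalize_transition_frame(raw: pd.DataFrame) -> pd.DataFrame:
    """Normalize column names/labels of an in-memory transition table."""
    required = ("peptide_id", "label", "replicate_id", "fragment_name", "area")
    cols = resolve_columns(raw.columns, TRANSITION_ALIASES, required=required)
    df = raw.rename(columns={v: k for k, v in cols.items()}).copy()
    if "background" not in df.columns:
        df["background"] = 0.0
    if "retention_time" not in df.columns:
        df["retention_time"] = np.nan

    df["label"] = df["label"].astype(str).str.strip().str.lower().map(
        lambda s: _LABEL_ALIASES.get(s, s)
    )
    bad_label = ~df["label"].isin([LIGHT, HEAVY])
    if bad_label.any():
        raise ValidationError(
            f"unmappable isotope label values in rows {df.index[bad_label].tolist()}"
        )

    bad_rows: list[int] = []
    for col in ("area", "background"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        unparseable = coerced.isna() & df[col].notna()
        negative = coerced < 0
        bad_rows.extend(df.index[unparseable | negative].tolist())
        df[col] = coerced
    if bad_rows:
        raise ValidationError(
            f"negative or unparseable area/background in rows {sorted(set(bad_rows))}"
        )
    df["retention_time"] = pd.to_numeric(df["retention_time"], errors="coerce")

    key = ["peptide_id", "label", "replicate_id", "fragment_name"]
    df["peptide_id"] = df["peptide_id"].astype(str)
    df["replicate_id"] = df["replicate_id"].astype(str)
    df["fragment_name"] = df["fragment_name"].astype(str)
    dup = df.duplicated(subset=key)
    if dup.any():
        raise ValidationError(f"duplicate (peptide, label, replicate, fragment) rows: {df.index[dup].tolist()}")
    return df


def frame_to_records(df: pd.DataFrame) -> list[TransitionRecord]:
    """Convert a tidy transition table to typed records."""
    core = {"peptide_id", "label", "replicate_id", "fragment_name", "area", "background", "retention_time"}
    ann_cols = [c for c in df.columns if c not in core]
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            TransitionRecord(
                peptide_id=d["peptide_id"],
                label=d["label"],
                replicate_id=d["replicate_id"],
                fragment_name=d["fragment_name"],
                area=float(d["area"]),
                background=float(d["background"]),
                retention_time=None if pd.isna(d.get("retention_time", np.nan)) else float(d["retention_time"]),
                sample_annotations={c: d[c] for c in ann_cols},
            )
        )
    return out


def records_to_frame(records: Iterable[TransitionRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        d = dataclasses.asdict(r)
        ann = d.pop("sample_annotations")
        d.update(ann)
        rows.append(d)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Characterization output
# ---------------------------------------------------------------------------


def write_characterization_table(
    results: pd.DataFrame,
    path: str | Path,
    overwrite: bool = False,
    metadata: Mapping[str, object] | None = None,
) -> Path:
    """Write the per-peptide characterization table (CSV or XLSX).

    One row per peptide x matrix: curve fit, LLOQ/ULOQ, dynamic range,
    intra/inter CVs per level, stability percent differences and the
    validation call. A JSON run-metadata sidecar is written next to the
    table when ``metadata`` is given. Refuses to clobber an existing file
    unless ``overwrite`` is set.
    """
    if results is None or len(results) == 0:
        raise ValueError("refusing to write an empty characterization table")
    path = Path(path)
    if path.exists() and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        results.to_excel(path, index=False, sheet_name="characterization")
    else:
        results.to_csv(path, index=False, float_format="%.6g")
    if metadata is not None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(dict(metadata), indent=2, default=str))
    return path


def read_characterization_table(path: str | Path) -> pd.DataFrame:
    """Read back a characterization table written by the matching writer."""
    return _clean_missing(_read_table(path))
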