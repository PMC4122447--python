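"""Tabular I/O: the protein intensity container and its on-disk layout.

The canonical on-disk form is a UTF-8, tab-separated file with a header row
and columns::

    Accession  GeneName  Description  Intensity.<experiment>.<tissue-code> ...

One intensity per protein per (experiment, tissue) sample, in arbitrary MS
intensity units.  A zero or empty intensity cell means "not detected in that
sample".  Foreign layouts (e.g. supplementary workbooks exported to TSV) are
adapted through a ``column_map`` that maps file column names onto
(experiment, tissue) pairs.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .tissues import ALL_TISSUES, Tissue

IDENTITY_COLUMNS = ("Accession", "GeneName", "Description")
_INTENSITY_RE = re.compile(r"^Intensity\.(?P<exp>[^.]+)\.(?P<tissue>[A-Za-z]+)$")


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------

@dataclass
class IntensityTable:
    """Protein x (experiment, tissue) nonnegative MS intensities.

    Parameters
    ----------
    values
        DataFrame indexed by accession with a two-level column MultiIndex
        ``(experiment, tissue_code)``; entries are finite and >= 0, with 0
        meaning not detected.
    meta
        Per-protein identity metadata (``GeneName``, ``Description``),
        indexed like ``values``.
    detected
        Boolean detection mask with the same shape as ``values``.  For raw
        tables this is simply ``values > 0``; after zero-imputation it
        preserves the pre-imputation detection pattern.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    detected: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.detected is None:
            self.detected = self.values > 0
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValidationError("intensities must be finite")
        if (vals < 0).any():
            rows = np.unique(np.nonzero(vals < 0)[0])
            raise ValidationError(
                f"negative intensity at row index {rows[0]} "
                f"(accession {self.values.index[rows[0]]!r})"
            )
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate accession {dup!r}")
        if (self.values.index == "").any():
            raise ValidationError("empty accession")
        if not self.values.index.equals(self.meta.index):
            raise ValidationError("meta index does not match values index")
        if not (
            self.detected.index.equals(self.values.index)
            and self.detected.columns.equals(self.values.columns)
        ):
            raise ValidationError("detection mask does not align with values")

    # -- basic geometry ----------------------------------------------------
    @property
    def accessions(self) -> pd.Index:
        return self.values.index

    @property
    def n_proteins(self) -> int:
        return len(self.values)

    @property
    def experiments(self) -> list[str]:
        return list(dict.fromkeys(self.values.columns.get_level_values(0)))

    @property
    def tissues(self) -> list[Tissue]:
        codes = pd.unique(self.values.columns.get_level_values(1))
        return [Tissue.from_code(c) for c in codes]

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    # -- views -------------------------------------------------------------
    def sample(self, experiment: str, tissue: Tissue) -> pd.Series:
        """Intensity vector of one (experiment, tissue) sample."""
        return self.values[(experiment, tissue.value)]

    def presence_by_experiment(self) -> pd.DataFrame:
        """Protein x experiment boolean: detected in >=1 tissue of that experiment."""
        return self.detected.T.groupby(level=0).any().T

    def replace(self, **kwargs) -> "IntensityTable":
        """Return a copy with some fields substituted."""
        data = {"values": self.values, "meta": self.meta, "detected": self.detected}
        data.update(kwargs)
        return IntensityTable(**data)

    def copy(self) -> "IntensityTable":
        return IntensityTable(self.values.copy(), self.meta.copy(), self.detected.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntensityTable):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.meta.equals(other.meta)
            and self.detected.equals(other.detected)
        )


def make_intensity_table(
    accessions: Sequence[str],
    intensities: np.ndarray,
    experiments: Sequence[str] | None = None,
    tissues: Sequence[Tissue] = ALL_TISSUES,
    gene_names: Sequence[str] | None = None,
    descriptions: Sequence[str] | None = None,
) -> IntensityTable:
    """Build an :class:`IntensityTable` from a dense (protein, experiment, tissue) array."""
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim != 3:
        raise ValidationError("intensities must be 3-dimensional (protein, experiment, tissue)")
    n_p, n_e, n_t = arr.shape
    if experiments is None:
        experiments = [f"E{i + 1}" for i in range(n_e)]
    if n_p != len(accessions) or n_e != len(experiments) or n_t != len(tissues):
        raise ValidationError("intensity array shape inconsistent with labels")
    cols = pd.MultiIndex.from_product(
        [list(experiments), [t.value for t in tissues]], names=["experiment", "tissue"]
    )
    values = pd.DataFrame(
        arr.reshape(n_p, n_e * n_t), index=pd.Index(accessions, name="Accession"),
        columns=cols,
    )
    meta = pd.DataFrame(
        {
            "GeneName": list(gene_names) if gene_names is not None else list(accessions),
            "Description": list(descriptions) if descriptions is not None else [""] * n_p,
        },
        index=values.index,
    )
    return IntensityTable(values, meta)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def default_column_map(
    experiments: Sequence[str], tissues: Sequence[Tissue] = ALL_TISSUES
) -> dict[str, tuple[str, Tissue]]:
    """The canonical ``Intensity.<experiment>.<tissue-code>`` column mapping."""
    return {
        f"Intensity.{e}.{t.value}": (e, t) for e in experiments for t in tissues
    }


def infer_column_map(columns: Iterable[str]) -> dict[str, tuple[str, Tissue]]:
    """Recognize canonical intensity columns present in a header."""
    cmap: dict[str, tuple[str, Tissue]] = {}
    for col in columns:
        m = _INTENSITY_RE.match(col)
        if m:
            try:
                tissue = Tissue.from_code(m.group("tissue"))
            except ValueError:
                continue
            cmap[col] = (m.group("exp"), tissue)
    return cmap


def read_intensity_table(
    path: str | Path,
    column_map: Mapping[str, tuple[str, Tissue | str]] | None = None,
) -> IntensityTable:
    """Read a protein intensity TSV.

    ``column_map`` maps file column names to (experiment, tissue) pairs; if
    omitted, canonical ``Intensity.<E>.<T>`` columns are auto-detected.
    Empty, ``NA`` and ``NaN`` intensity cells are read as 0 (not detected).
    """
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", dtype={c: str for c in IDENTITY_COLUMNS},
        float_precision="round_trip",
    )
    for col in IDENTITY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing identity column {col!r} in {path}")
    if column_map is None:
        column_map = infer_column_map(df.columns)
        if not column_map:
            raise FormatError(f"no canonical intensity columns found in {path}")
    norm_map: dict[str, tuple[str, Tissue]] = {}
    for col, (exp, tissue) in column_map.items():
        if col not in df.columns:
            raise FormatError(f"missing mapped intensity column {col!r} in {path}")
        norm_map[col] = (str(exp), tissue if isinstance(tissue, Tissue) else Tissue.from_code(tissue))

    experiments = list(dict.fromkeys(e for e, _ in norm_map.values()))
    tissues = list(dict.fromkeys(t for _, t in norm_map.values()))

    accessions = df["Accession"].fillna("")
    if accessions.duplicated().any():
        dup = accessions[accessions.duplicated()].iloc[0]
        raise ValidationError(f"duplicate accession {dup!r} in {path}")

    intens = pd.DataFrame(index=df.index)
    for col, (exp, tissue) in norm_map.items():
        raw = pd.to_numeric(df[col], errors="coerce")
        raw = raw.fillna(0.0)
        neg = raw[raw < 0]
        if len(neg):
            raise ValidationError(
                f"negative intensity in column {col!r}, row {int(neg.index[0])} of {path}"
            )
        intens[(exp, tissue.value)] = raw.astype(float)
    cols = pd.MultiIndex.from_product(
        [experiments, [t.value for t in tissues]], names=["experiment", "tissue"]
    )
    # reorder to canonical (experiment, tissue) nesting; all pairs must exist
    missing = [c for c in cols if c not in intens.columns]
    if missing:
        raise FormatError(
            f"column_map does not cover all (experiment, tissue) pairs; missing {missing}"
        )
    intens = intens[list(cols)]
    intens.columns = cols
    intens.index = pd.Index(accessions, name="Accession")
    meta = pd.DataFrame(
        {
            "GeneName": df["GeneName"].fillna("").to_numpy(),
            "Description": df["Description"].fillna("").to_numpy(),
        },
        index=intens.index,
    )
    return IntensityTable(intens, meta)


def write_intensity_table(table: IntensityTable, path: str | Path) -> None:
    """Write an :class:`IntensityTable` in the canonical TSV layout.

    Intensities are serialized with ``repr`` round-trip precision so that
    ``read(write(x)) == x`` for any representable value.
    """
    path = Path(path)
    out = pd.DataFrame(index=table.values.index)
    out["Accession"] = table.values.index
    out["GeneName"] = table.meta["GeneName"]
    out["Description"] = table.meta["Description"]
    for exp, code in table.values.columns:
        out[f"Intensity.{exp}.{code}"] = table.values[(exp, code)]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# results serialization
# ---------------------------------------------------------------------------

GROUP_LABELS = {"A": "a", "B": "b", "B_triplicate": "b(t)", "none": ""}


def format_sig(x: float, sig: int = 3) -> str:
    """Format to ``sig`` significant figures, plain decimal where possible."""
    if x == 0 or not math.isfinite(x):
        return str(x)
    from decimal import Decimal

    rounded = float(f"{x:.{sig}g}")
    if abs(rounded) >= 1e6 or abs(rounded) < 1e-4:
        return f"{x:.{sig}g}"
    return format(Decimal(f"{x:.{sig}g}").normalize(), "f")


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write a differential-comparison or ranked results table as TSV.

    Fold-change columns (named ``fold_change`` or ending in ``_fc``) are
    serialized to 3 significant figures; group labels use the compact
    notation ``a`` / ``b`` / ``b(t)`` / ``""``.
    """
    if results is None or len(results) == 0:
        raise ValidationError("refusing to write an empty results table")
    out = results.copy()
    for col in out.columns:
        name = str(col)
        if name == "fold_change" or name.endswith("_fc"):
            out[col] = [format_sig(v, 3) if pd.notna(v) else "" for v in out[col]]
        if name == "group" or name.endswith("_group"):
            out[col] = [GROUP_LABELS.get(str(v), str(v)) for v in out[col]]
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# config + workbook conversion helpers
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Read a flat YAML configuration file into a dict."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise FormatError(f"configuration {path} must be a mapping")
    return cfg


def parse_column_map(cfg: Mapping[str, str]) -> dict[str, tuple[str, Tissue]]:
    """Parse a config-style column map ``{file column: "<exp>:<tissue>"}``."""
    cmap: dict[str, tuple[str, Tissue]] = {}
    for col, entry in cfg.items():
        try:
            exp, code = str(entry).split(":")
        except ValueError:
            raise FormatError(
                f"column map entry {col!r}: expected '<experiment>:<tissue-code>', got {entry!r}"
            ) from None
        cmap[col] = (exp, Tissue.from_code(code))
    return cmap


def convert_xlsx(path: str | Path, out_path: str | Path, sheet: int | str = 0) -> None:
    """Convert one sheet of a workbook to TSV for the core reader.

    Workbook inputs (e.g. supplementary quantitative tables) are supported
    only through this explicit conversion; the core reader handles a single
    TSV dialect bit-exactly.
    """
    df = pd.read_excel(path, sheet_name=sheet)
    df.to_csv(out_path, sep="\t", index=False)
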