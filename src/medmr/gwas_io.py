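"""Reading, validating and writing GWAS summary statistics and LD references.

Summary statistics are tab-separated, one row per variant, with the nine
canonical columns (any order)::

    variant_id  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

``eaf`` may be missing (empty field). Effect sizes are log odds ratios for
binary traits and SD units for quantitative traits. A reference genotype
panel is a plain TSV dosage matrix (individuals x variants, header row of
variant ids); a precomputed LD matrix TSV (square, matching header and row
names) may be supplied instead.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: floats are written with 10 significant digits everywhere
FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Malformed input file (missing column, empty file, ...)."""


class LookupError_(KeyError):
    """A requested variant id is absent from a panel or LD matrix."""


class DegenerateInputError(ValueError):
    """Numerically degenerate input, e.g. a zero-variance dosage column."""


@dataclass(frozen=True)
class SummaryRecord:
    """Per-variant GWAS summary statistics for one trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float

    def zscore(self) -> float:
        return self.beta / self.se

    def is_palindromic(self) -> bool:
        """A/T or C/G SNP; indel alleles are never treated as palindromic."""
        a, b = self.effect_allele, self.other_allele
        if len(a) != 1 or len(b) != 1:
            return False
        return {a, b} in ({"A", "T"}, {"C", "G"})


@dataclass
class SummaryTable:
    """Validated GWAS summary statistics for a single trait.

    Records are unique by ``variant_id`` and sorted by ``(chrom, pos)``.
    """

    trait_id: str
    trait_type: str  # "quantitative" | "binary"
    records: list[SummaryRecord] = field(default_factory=list)
    case_count: int | None = None
    control_count: int | None = None
    n_dropped: int = 0  # rows removed during validation

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        ids = [r.variant_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate variant ids in table {self.trait_id!r}")
        self.records = sorted(self.records, key=lambda r: (r.chrom, r.pos))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, variant_id: str) -> SummaryRecord | None:
        return self._index().get(variant_id)

    def _index(self) -> dict[str, SummaryRecord]:
        if not hasattr(self, "_idx") or len(self._idx) != len(self.records):
            self._idx = {r.variant_id: r for r in self.records}
        return self._idx

    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.records]

    def subset(self, ids: Iterable[str]) -> "SummaryTable":
        keep = set(ids)
        return SummaryTable(
            trait_id=self.trait_id,
            trait_type=self.trait_type,
            records=[r for r in self.records if r.variant_id in keep],
            case_count=self.case_count,
            control_count=self.control_count,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": [r.variant_id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "pos": [r.pos for r in self.records],
                "effect_allele": [r.effect_allele for r in self.records],
                "other_allele": [r.other_allele for r in self.records],
                "eaf": [np.nan if r.eaf is None else r.eaf for r in self.records],
                "beta": [r.beta for r in self.records],
                "se": [r.se for r in self.records],
                "pval": [r.pval for r in self.records],
                "n": [r.n for r in self.records],
            }
        )


@dataclass
class ReferencePanel:
    """Individuals x variants dosage matrix (values in [0, 2])."""

    variant_ids: list[str]
    dosages: np.ndarray
    positions: dict[str, tuple[str, int]] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.variant_ids):
            raise ValueError("dosage matrix shape does not match variant id count")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def column(self, variant_id: str) -> np.ndarray:
        try:
            j = self.variant_ids.index(variant_id)
        except ValueError:
            raise LookupError_(f"variant {variant_id!r} not in panel") from None
        return self.dosages[:, j]


@dataclass
class LDMatrix:
    """Pearson correlations between variant dosages; diagonal 1, symmetric."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match variant count")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-8):
            raise ValueError("LD matrix diagonal is not 1")
        self._idx = {v: i for i, v in enumerate(self.variant_ids)}

    def index_of(self, variant_id: str) -> int:
        try:
            return self._idx[variant_id]
        except KeyError:
            raise LookupError_(f"variant {variant_id!r} not in LD matrix") from None

    def r_between(self, a: str, b: str) -> float:
        return float(self.r[self.index_of(a), self.index_of(b)])

    def r2_between(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2

    def subset(self, ids: Sequence[str]) -> "LDMatrix":
        idx = [self.index_of(v) for v in ids]
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# summary-statistic I/O


def _validate_row(row: Mapping, z_pval_rtol: float = 0.10) -> SummaryRecord | None:
    """Return a validated record or None if the row violates an invariant."""
    try:
        ea = str(row["effect_allele"]).upper().strip()
        oa = str(row["other_allele"]).upper().strip()
        se = float(row["se"])
        beta = float(row["beta"])
        pval = float(row["pval"])
        pos = int(row["pos"])
        n = float(row["n"])
        eaf_raw = row["eaf"]
        eaf = None if pd.isna(eaf_raw) else float(eaf_raw)
    except (TypeError, ValueError):
        return None
    if not np.isfinite(se) or se <= 0:
        return None
    if not np.isfinite(beta):
        return None
    if not (0 < pval <= 1):
        return None
    if eaf is not None and not (0 <= eaf <= 1):
        return None
    if ea == oa or not ea or not oa:
        return None
    if n <= 0 or pos <= 0:
        return None
    # consistency of stated p with |z|: warn but keep the stated value
    z = abs(beta / se)
    p_from_z = 2 * stats.norm.sf(z)
    if p_from_z > 1e-300 and pval > 1e-300:
        if abs(np.log(p_from_z) - np.log(pval)) > 0.5 and abs(p_from_z - pval) > z_pval_rtol * pval:
            logger.warning(
                "variant %s: stated pval %.3g differs from z-implied %.3g; keeping stated",
                row["variant_id"], pval, p_from_z,
            )
    return SummaryRecord(
        variant_id=str(row["variant_id"]),
        chrom=str(row["chrom"]),
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval,
        n=n,
    )


def read_summary_table(
    path: str | Path,
    trait_id: str | None = None,
    trait_type: str = "quantitative",
    case_count: int | None = None,
    control_count: int | None = None,
) -> SummaryTable:
    """Read a summary-statistic TSV into a validated :class:`SummaryTable`.

    Rows violating record invariants (se <= 0, pval out of (0,1], identical
    alleles, ...) are dropped with a logged count, never silently.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "chrom": str}, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty summary-statistic file") from None
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if len(df) == 0:
        raise FormatError(f"{path}: summary-statistic file has a header but no rows")
    records: list[SummaryRecord] = []
    n_dropped = 0
    for row in df.to_dict("records"):
        rec = _validate_row(row)
        if rec is None:
            n_dropped += 1
        else:
            records.append(rec)
    if n_dropped:
        logger.info("%s: dropped %d invalid row(s) of %d", path, n_dropped, len(df))
    table = SummaryTable(
        trait_id=trait_id or path.stem,
        trait_type=trait_type,
        records=records,
        case_count=case_count,
        control_count=control_count,
    )
    table.n_dropped = n_dropped
    return table


def write_summary_table(table: SummaryTable, path: str | Path, header_meta: Mapping | None = None) -> None:
    """Write a summary table as TSV (10 significant digits, `#`-prefixed metadata)."""
    path = Path(path)
    with open(path, "w") as fh:
        if header_meta:
            for k, v in header_meta.items():
                fh.write(f"# {k}: {v}\n")
        table.to_frame().to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


# ---------------------------------------------------------------------------
# reference panel / LD


def read_panel(path: str | Path, positions: Mapping[str, tuple[str, int]] | None = None) -> ReferencePanel:
    """Read a dosage-matrix TSV (header row of variant ids)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise FormatError(f"{path}: empty reference panel")
    dosages = df.to_numpy(dtype=float)
    if np.nanmin(dosages) < 0 or np.nanmax(dosages) > 2:
        raise FormatError(f"{path}: dosages outside [0, 2]")
    return ReferencePanel(list(df.columns), dosages, dict(positions) if positions else None)


def write_panel(panel: ReferencePanel, path: str | Path, header_meta: Mapping | None = None) -> None:
    with open(path, "w") as fh:
        if header_meta:
            for k, v in header_meta.items():
                fh.write(f"# {k}: {v}\n")
        pd.DataFrame(panel.dosages, columns=panel.variant_ids).to_csv(
            fh, sep="\t", index=False, float_format=FLOAT_FMT
        )


def compute_ld(panel: ReferencePanel, ids: Sequence[str] | None = None) -> LDMatrix:
    """Pearson correlation matrix of the requested dosage columns.

    Raises :class:`DegenerateInputError` naming the first zero-variance
    variant, and :class:`LookupError_` for ids absent from the panel.
    """
    ids = list(ids) if ids is not None else list(panel.variant_ids)
    col_index = {v: j for j, v in enumerate(panel.variant_ids)}
    missing = [v for v in ids if v not in col_index]
    if missing:
        raise LookupError_(f"variant(s) not in panel: {', '.join(missing[:5])}")
    g = panel.dosages[:, [col_index[v] for v in ids]]
    sd = g.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        raise DegenerateInputError(f"zero-variance dosage column: {ids[zero[0]]!r}")
    r = np.corrcoef(g, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    return LDMatrix(ids, r)


def read_ld(path: str | Path) -> LDMatrix:
    """Read a precomputed square LD TSV (matching header and row names)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if list(df.columns) != list(df.index.astype(str)):
        raise FormatError(f"{path}: LD matrix header and row names do not match")
    return LDMatrix(list(df.columns), df.to_numpy(dtype=float))


def write_ld(ld: LDMatrix, path: str | Path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t", float_format=FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# result reporting


def _result_frame(results: Sequence) -> pd.DataFrame:
    rows = []
    for res in results:
        if hasattr(res, "to_row"):
            rows.append(res.to_row())
        elif isinstance(res, Mapping):
            rows.append(dict(res))
        else:
            rows.append(vars(res))
    return pd.DataFrame(rows)


def write_report(
    results: Sequence | Mapping[str, Sequence],
    path: str | Path,
    header_meta: Mapping | None = None,
) -> list[Path]:
    """Write results as TSV + JSON with stable column order.

    ``results`` is either one homogeneous sequence, or a mapping from result
    kind to sequence, in which case one file pair per kind is emitted with the
    kind appended to the stem. Returns the paths written.
    """
    path = Path(path)
    if isinstance(results, Mapping):
        written: list[Path] = []
        for kind, seq in results.items():
            out = path.with_name(f"{path.stem}_{kind}{path.suffix or '.tsv'}")
            written.extend(write_report(seq, out, header_meta))
        return written
    results = list(results)
    if not results:
        raise ValueError("write_report requires a non-empty result collection")
    df = _result_frame(results)
    tsv = path if path.suffix == ".tsv" else path.with_suffix(".tsv")
    with open(tsv, "w") as fh:
        if header_meta:
            for k, v in header_meta.items():
                fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)
    jsn = tsv.with_suffix(".json")
    payload = {"meta": dict(header_meta or {}), "results": json.loads(df.to_json(orient="records"))}
    jsn.write_text(json.dumps(payload, indent=1, default=str))
    return [tsv, jsn]
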