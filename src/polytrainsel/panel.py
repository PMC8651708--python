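"""Dosage panels, phenotype tables and marker quality control.

The central container is :class:`DosagePanel`: an individuals x markers
matrix of integer allele dosages for an autopolyploid of ploidy ``q``
(tetraploid by default, so entries run 0..4 and count copies of the
alternate "B" allele; the genotype AAAB corresponds to dosage 1).  Missing
calls are carried as a boolean mask and are never imputed at this layer --
downstream consumers (distances, kinship) each apply their own documented
handling.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DosagePanel",
    "TraitSet",
    "QCReport",
    "PanelFormatError",
    "PanelValidationError",
    "read_dosage_panel",
    "write_dosage_panel",
    "read_phenotypes",
    "write_phenotypes",
    "read_square_matrix",
    "write_square_matrix",
    "qc_filter",
]


class PanelFormatError(ValueError):
    """Malformed input file (non-integer dosage, out-of-range value, ...)."""


class PanelValidationError(ValueError):
    """Structurally invalid panel (duplicate ids, shape mismatch, ...)."""


MISSING_TOKEN = "NA"


@dataclasses.dataclass
class DosagePanel:
    """Individuals x markers integer dosage matrix with map metadata.

    Parameters
    ----------
    genotype_ids
        Unique individual identifiers (rows).
    dosages
        Integer array ``(n_individuals, n_markers)``; entries in ``[0, q]``.
        Entries under ``missing`` are ignored.
    ploidy
        Even chromosome copy number ``q`` (4 for autotetraploids).
    marker_ids, chrom, pos
        Marker map metadata; ``pos`` is 1-based, ``chrom`` of ``"0"`` or
        ``""`` marks an unmapped marker.
    strata
        Optional per-individual subpopulation label.
    missing
        Boolean mask, True where the dosage call is missing.
    """

    genotype_ids: list[str]
    dosages: np.ndarray
    ploidy: int = 4
    marker_ids: list[str] | None = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None
    strata: np.ndarray | None = None
    missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        if self.dosages.ndim != 2:
            raise PanelValidationError("dosages must be 2-D (individuals x markers)")
        n, m = self.dosages.shape
        self.genotype_ids = [str(g) for g in self.genotype_ids]
        if len(self.genotype_ids) != n:
            raise PanelValidationError(
                f"{len(self.genotype_ids)} genotype ids for {n} dosage rows"
            )
        if len(set(self.genotype_ids)) != n:
            raise PanelValidationError("duplicate genotype ids")
        if self.marker_ids is None:
            self.marker_ids = [f"M{j + 1}" for j in range(m)]
        self.marker_ids = [str(s) for s in self.marker_ids]
        if len(self.marker_ids) != m:
            raise PanelValidationError(
                f"{len(self.marker_ids)} marker ids for {m} dosage columns"
            )
        if len(set(self.marker_ids)) != m:
            raise PanelValidationError("duplicate marker ids")
        if self.ploidy <= 0 or self.ploidy % 2:
            raise PanelValidationError(f"ploidy must be a positive even integer, got {self.ploidy}")
        if self.missing is None:
            self.missing = np.zeros((n, m), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (n, m):
                raise PanelValidationError("missing mask shape mismatch")
        if not np.issubdtype(self.dosages.dtype, np.integer):
            vals = self.dosages[~self.missing]
            if vals.size and not np.all(vals == np.round(vals)):
                raise PanelFormatError("non-integer dosage values")
            d = np.array(self.dosages, dtype=float)
            d[self.missing] = 0
            self.dosages = d.astype(np.int16)
        observed = self.dosages[~self.missing]
        if observed.size and (observed.min() < 0 or observed.max() > self.ploidy):
            bad = np.argwhere(
                (~self.missing)
                & ((self.dosages < 0) | (self.dosages > self.ploidy))
            )[0]
            raise PanelFormatError(
                f"dosage out of range [0, {self.ploidy}] at individual "
                f"'{self.genotype_ids[bad[0]]}', marker '{self.marker_ids[bad[1]]}'"
            )
        for name in ("chrom", "pos"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                if v.shape != (m,):
                    raise PanelValidationError(f"{name} length mismatch")
                setattr(self, name, v)
        if self.strata is not None:
            self.strata = np.asarray(self.strata)
            if self.strata.shape != (n,):
                raise PanelValidationError("strata length mismatch")

    # -- convenience ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per marker: mean(dosage)/q over non-missing."""
        d = np.where(self.missing, np.nan, self.dosages.astype(float))
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / self.ploidy

    def dosage_float(self, fill: float | None = None) -> np.ndarray:
        """Dosages as float with missing entries NaN (or ``fill``)."""
        d = self.dosages.astype(float)
        d[self.missing] = np.nan if fill is None else fill
        return d

    def subset_markers(self, idx: Sequence[int] | np.ndarray) -> "DosagePanel":
        idx = np.asarray(idx)
        return DosagePanel(
            genotype_ids=list(self.genotype_ids),
            dosages=self.dosages[:, idx],
            ploidy=self.ploidy,
            marker_ids=[self.marker_ids[j] for j in idx],
            chrom=None if self.chrom is None else self.chrom[idx],
            pos=None if self.pos is None else self.pos[idx],
            strata=self.strata,
            missing=self.missing[:, idx],
        )

    def subset_individuals(self, idx: Sequence[int] | np.ndarray) -> "DosagePanel":
        idx = np.asarray(idx)
        return DosagePanel(
            genotype_ids=[self.genotype_ids[i] for i in idx],
            dosages=self.dosages[idx],
            ploidy=self.ploidy,
            marker_ids=list(self.marker_ids),
            chrom=self.chrom,
            pos=self.pos,
            strata=None if self.strata is None else self.strata[idx],
            missing=self.missing[idx],
        )

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.genotype_ids)}
        try:
            return np.array([lookup[str(g)] for g in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise PanelValidationError(f"unknown genotype id {exc}") from exc

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DosagePanel):
            return NotImplemented
        same_meta = (
            self.genotype_ids == other.genotype_ids
            and self.marker_ids == other.marker_ids
            and self.ploidy == other.ploidy
        )
        if not same_meta:
            return False
        obs = ~self.missing
        return bool(
            np.array_equal(self.missing, other.missing)
            and np.array_equal(self.dosages[obs], other.dosages[obs])
        )


@dataclasses.dataclass
class TraitSet:
    """Per-individual phenotypic BLUEs for one trait, plus simulation truth.

    ``heritability`` is the broad-sense h2 on record for the trait; it feeds
    the CDmean shrinkage ratio and, for simulated traits, is the generator's
    target.  ``genetic_values`` / ``qtl_indices`` / ``qtl_effects`` are only
    present for synthetic traits.
    """

    genotype_ids: list[str]
    values: np.ndarray
    trait_name: str = "trait"
    heritability: float | None = None
    genetic_values: np.ndarray | None = None
    qtl_indices: np.ndarray | None = None
    qtl_effects: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genotype_ids),):
            raise PanelValidationError("phenotype length does not match ids")
        if self.heritability is not None and not (0 < self.heritability <= 1):
            raise PanelValidationError("heritability must lie in (0, 1]")

    def series(self) -> pd.Series:
        return pd.Series(self.values, index=self.genotype_ids, name=self.trait_name)

    def realized_h2(self) -> float | None:
        """Sample variance ratio var(g)/var(y) of the stored truth."""
        if self.genetic_values is None:
            return None
        return float(np.var(self.genetic_values, ddof=1) / np.var(self.values, ddof=1))


@dataclasses.dataclass
class QCReport:
    """Marker counts from quality control.

    ``n_monomorphic``/``n_unmapped``/``n_low_maf``/``n_high_missing`` use
    first-failure attribution in that order, so they sum to the number of
    removed markers; ``failed_any`` counts per-filter failures regardless of
    attribution (a marker may fail several filters).
    """

    n_input: int
    n_monomorphic: int
    n_unmapped: int
    n_low_maf: int
    n_high_missing: int
    n_retained: int
    failed_any: dict[str, int]
    thresholds: dict[str, float | int | bool]

    def __post_init__(self) -> None:
        removed = (
            self.n_monomorphic + self.n_unmapped + self.n_low_maf + self.n_high_missing
        )
        assert self.n_retained + removed == self.n_input

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _map_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(".map.tsv") if p.suffix else Path(str(p) + ".map.tsv")


def read_dosage_panel(
    path: str | Path,
    format: str = "tsv",
    ploidy: int = 4,
    map_path: str | Path | None = None,
    strata_path: str | Path | None = None,
) -> DosagePanel:
    """Read a dosage panel from a delimited file or a VCF.

    The TSV dialect has individuals as rows: first column the genotype id,
    remaining columns integer dosages (header row = marker ids, ``NA`` =
    missing).  A sidecar map file ``<path>.map.tsv`` (columns marker_id,
    chrom, pos) is picked up automatically when present.  The VCF dialect
    takes per-sample dosages from the ``DS`` FORMAT field when present,
    otherwise by counting alternate alleles in a tetraploid ``GT``.
    """
    if format == "tsv":
        panel = _read_tsv(path, ploidy, map_path)
    elif format == "vcf":
        panel = _read_vcf(path, ploidy)
    else:
        raise ValueError(f"unknown format {format!r}")
    if strata_path is not None:
        strata = pd.read_csv(strata_path, dtype=str).set_index("id")["stratum"]
        panel.strata = strata.reindex(panel.genotype_ids).to_numpy()
    return panel


def _read_tsv(path: str | Path, ploidy: int, map_path: str | Path | None) -> DosagePanel:
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    marker_ids = list(df.columns)
    raw = df.to_numpy()
    missing = (raw == MISSING_TOKEN) | pd.isna(raw)
    dosages = np.zeros(raw.shape, dtype=np.int16)
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            if missing[i, j]:
                continue
            try:
                v = int(raw[i, j])
            except (TypeError, ValueError):
                raise PanelFormatError(
                    f"non-integer dosage {raw[i, j]!r} at row '{df.index[i]}', "
                    f"column '{marker_ids[j]}'"
                ) from None
            dosages[i, j] = v
    chrom = pos = None
    mp = Path(map_path) if map_path is not None else _map_path(path)
    if mp.exists():
        mdf = pd.read_csv(mp, sep="\t", dtype={"marker_id": str, "chrom": str})
        mdf = mdf.set_index("marker_id").reindex(marker_ids)
        chrom = mdf["chrom"].fillna("0").to_numpy()
        pos = mdf["pos"].fillna(0).to_numpy(dtype=int)
    return DosagePanel(
        genotype_ids=list(df.index),
        dosages=dosages,
        ploidy=ploidy,
        marker_ids=marker_ids,
        chrom=chrom,
        pos=pos,
        missing=missing,
    )


def _read_vcf(path: str | Path, ploidy: int) -> DosagePanel:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    ids = list(vcf.samples)
    marker_ids: list[str] = []
    chrom: list[str] = []
    pos: list[int] = []
    cols: list[np.ndarray] = []
    miss: list[np.ndarray] = []
    source = None  # all records must use the same dosage source
    for var in vcf:
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            rec_source = "DS"
            vals = ds.astype(float).reshape(len(ids))
            m = ~np.isfinite(vals)
            d = np.round(np.where(m, 0, vals)).astype(np.int16)
        else:
            rec_source = "GT"
            gt = var.genotype.array()  # (n, ploidy+1); last column phasing
            alleles = gt[:, :-1]
            m = (alleles < 0).any(axis=1)
            d = np.where(m, 0, (alleles == 1).sum(axis=1)).astype(np.int16)
        if source is None:
            source = rec_source
        elif source != rec_source:
            raise PanelFormatError(
                "mixed dosage sources in VCF (some records DS, some GT-only)"
            )
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        chrom.append(str(var.CHROM))
        pos.append(int(var.POS))
        cols.append(d)
        miss.append(m)
    if not cols:
        raise PanelFormatError("VCF contains no variant records")
    return DosagePanel(
        genotype_ids=ids,
        dosages=np.column_stack(cols),
        ploidy=ploidy,
        marker_ids=marker_ids,
        chrom=np.array(chrom),
        pos=np.array(pos, dtype=int),
        missing=np.column_stack(miss),
    )


def write_dosage_panel(panel: DosagePanel, path: str | Path, format: str = "tsv") -> None:
    """Write a panel as dosage TSV (+ sidecar map) or as a minimal VCF (DS field)."""
    if format == "tsv":
        _write_tsv(panel, path)
    elif format == "vcf":
        _write_vcf(panel, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_tsv(panel: DosagePanel, path: str | Path) -> None:
    cells = panel.dosages.astype(object)
    cells[panel.missing] = MISSING_TOKEN
    df = pd.DataFrame(cells, index=panel.genotype_ids, columns=panel.marker_ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t")
    if panel.chrom is not None:
        pd.DataFrame(
            {"marker_id": panel.marker_ids, "chrom": panel.chrom, "pos": panel.pos}
        ).to_csv(_map_path(path), sep="\t", index=False)


def _write_vcf(panel: DosagePanel, path: str | Path) -> None:
    lines = [
        "##fileformat=VCFv4.2",
        f"##source=polytrainsel (ploidy={panel.ploidy})",
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(panel.genotype_ids),
    ]
    chrom = panel.chrom if panel.chrom is not None else np.array(["1"] * panel.n_markers)
    pos = panel.pos if panel.pos is not None else np.arange(1, panel.n_markers + 1)
    for j in range(panel.n_markers):
        calls = [
            "." if panel.missing[i, j] else str(int(panel.dosages[i, j]))
            for i in range(panel.n_individuals)
        ]
        c = str(chrom[j]) if str(chrom[j]) not in ("", "0") else "0"
        lines.append(
            f"{c}\t{int(pos[j])}\t{panel.marker_ids[j]}\tA\tB\t.\tPASS\t.\tDS\t"
            + "\t".join(calls)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Phenotype CSV with columns id, trait, value (long format)."""
    df = pd.read_csv(path, dtype={"id": str, "trait": str})
    required = {"id", "trait", "value"}
    if not required.issubset(df.columns):
        raise PanelFormatError(f"phenotype file must have columns {sorted(required)}")
    return df


def write_phenotypes(traits: Sequence[TraitSet], path: str | Path) -> None:
    rows = []
    for t in traits:
        for g, v in zip(t.genotype_ids, t.values):
            rows.append({"id": g, "trait": t.trait_name, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_square_matrix(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise PanelFormatError("square matrix file must have matching row/column ids")
    return [str(i) for i in df.index], df.to_numpy(dtype=float)


def write_square_matrix(ids: Sequence[str], values: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(values, index=list(ids), columns=list(ids)).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def qc_filter(
    panel: DosagePanel,
    maf_min: float = 0.05,
    max_missing_individuals: int | None = 30,
    max_missing_frac: float | None = None,
    drop_unmapped: bool = True,
    drop_monomorphic: bool = True,
) -> tuple[DosagePanel, QCReport]:
    """Apply marker QC: monomorphic, unmapped, low-MAF and high-missingness.

    MAF uses a strict inequality (markers exactly at ``maf_min`` are kept);
    missingness removes markers missing in strictly more than
    ``max_missing_individuals`` individuals (or fraction ``max_missing_frac``
    if given instead).  Allele frequency of marker j is mean(dosage_j)/q over
    non-missing individuals.
    """
    n, m = panel.dosages.shape
    if max_missing_frac is not None:
        max_missing_individuals = int(np.floor(max_missing_frac * n))
    d = panel.dosage_float()

    with np.errstate(invalid="ignore"):
        n_obs = (~panel.missing).sum(axis=0)
        mono = np.zeros(m, dtype=bool)
        for j in range(m):
            vals = d[~panel.missing[:, j], j]
            mono[j] = vals.size == 0 or np.all(vals == vals[0])
        freq = panel.allele_frequencies()
        maf = np.minimum(freq, 1 - freq)
    unmapped = np.zeros(m, dtype=bool)
    if panel.chrom is not None:
        cs = np.array([str(c) for c in panel.chrom])
        unmapped = (cs == "0") | (cs == "") | (cs == "nan")
    low_maf = maf < maf_min
    n_missing = n - n_obs
    high_missing = (
        n_missing > max_missing_individuals
        if max_missing_individuals is not None
        else np.zeros(m, dtype=bool)
    )
    if not drop_monomorphic:
        mono[:] = False
    if not drop_unmapped:
        unmapped[:] = False

    # first-failure attribution in the order monomorphic, unmapped, MAF, missing
    fail_mono = mono
    fail_unmap = unmapped & ~fail_mono
    fail_maf = low_maf & ~mono & ~unmapped
    fail_miss = high_missing & ~mono & ~unmapped & ~low_maf
    removed = mono | unmapped | low_maf | high_missing
    keep = ~removed
    if not keep.any():
        raise PanelValidationError("QC removed every marker (empty panel)")
    report = QCReport(
        n_input=m,
        n_monomorphic=int(fail_mono.sum()),
        n_unmapped=int(fail_unmap.sum()),
        n_low_maf=int(fail_maf.sum()),
        n_high_missing=int(fail_miss.sum()),
        n_retained=int(keep.sum()),
        failed_any={
            "monomorphic": int(mono.sum()),
            "unmapped": int(unmapped.sum()),
            "low_maf": int(low_maf.sum()),
            "high_missing": int(high_missing.sum()),
        },
        thresholds={
            "maf_min": maf_min,
            "max_missing_individuals": -1
            if max_missing_individuals is None
            else int(max_missing_individuals),
            "drop_unmapped": drop_unmapped,
            "drop_monomorphic": drop_monomorphic,
        },
    )
    return panel.subset_markers(np.flatnonzero(keep)), report
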