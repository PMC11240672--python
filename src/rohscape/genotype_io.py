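"""Read, write, merge and quality-filter SNP-array genotypes in PLINK formats.

Both the text (.ped/.map) and binary (.bed/.bim/.fam, SNP-major) layouts are
supported.  After loading, every dataset is recoded so that the dosage counts
the *dataset minor allele*: ``allele1`` in the marker table is the rarer allele
and a genotype of 2 means homozygous for it.  Homozygote/heterozygote status —
all the ROH and F_HOM machinery needs — is invariant to this choice, but a
fixed convention keeps allele frequencies comparable across operations.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import (
    MISSING,
    OVINE_AUTOSOMES,
    GenotypeDataset,
    ParseError,
    QCError,
    sort_markers,
)

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes (SNP-major): 00 hom allele1, 01 missing, 10 het, 11 hom allele2.
# Dosage of allele1 per code:
_BED_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_BED_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

# Byte -> 4 genotypes lookup table, lowest-order bit pair first.
_BYTE_LUT = np.array(
    [[_BED_CODE_TO_DOSAGE[(b >> (2 * k)) & 0b11] for k in range(4)] for b in range(256)],
    dtype=np.int8,
)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_plink(path_prefix: str | Path, format: str | None = None) -> GenotypeDataset:
    """Read a PLINK fileset ``prefix.{ped,map}`` or ``prefix.{bed,bim,fam}``.

    Parameters
    ----------
    path_prefix
        Path without extension.
    format
        ``"text"``, ``"binary"`` or ``None`` to autodetect (binary preferred
        when both exist).

    Returns
    -------
    GenotypeDataset
        Markers sorted by (chromosome, position); dosages recoded so that
        ``allele1`` is the dataset minor allele.
    """
    prefix = Path(path_prefix)
    if format is None:
        format = "binary" if prefix.with_suffix(".bed").exists() else "text"
    if format == "text":
        # .ped carries no allele order; count the minor allele (ties broken
        # lexicographically), which is this package's coding convention
        ds = recode_to_minor(_read_text(prefix))
    elif format == "binary":
        # .bim fixes the counted allele (A1); honored so that binary files
        # round-trip exactly whatever their coding
        ds = _read_binary(prefix)
    else:
        raise ValueError(f"unknown PLINK format {format!r}")
    ds = _sort_dataset(ds)
    ds.validate()
    return ds


def _read_map(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"missing map file: {path}")
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 4:
            raise ParseError(f"{path}:{ln}: expected 4 columns, got {len(parts)}")
        rows.append((parts[0], parts[1], int(parts[3])))
    df = pd.DataFrame(rows, columns=["chromosome", "snp_id", "position_bp"])
    df["position_bp"] = df["position_bp"].astype(np.int64)
    return df


def _read_text(prefix: Path) -> GenotypeDataset:
    mp = _read_map(prefix.with_suffix(".map"))
    ped = prefix.with_suffix(".ped")
    if not ped.exists():
        raise ParseError(f"missing ped file: {ped}")
    m = len(mp)
    sample_ids, populations, allele_rows = [], [], []
    for ln, line in enumerate(ped.read_text().splitlines(), 1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6 + 2 * m:
            raise ParseError(
                f"{ped}:{ln}: expected {6 + 2 * m} fields for {m} map SNPs, got {len(parts)}"
            )
        populations.append(parts[0])
        sample_ids.append(parts[1])
        allele_rows.append(parts[6:])
    if not sample_ids:
        raise ParseError(f"{ped}: no samples")
    alleles = np.array(allele_rows, dtype=object).reshape(len(sample_ids), m, 2)

    genotypes = np.full((len(sample_ids), m), MISSING, dtype=np.int8)
    a1_codes, a2_codes = [], []
    for j in range(m):
        col = alleles[:, j, :]
        called = col != "0"
        codes = sorted(set(col[called].tolist()))
        if len(codes) > 2:
            raise ParseError(
                f"{ped}: marker {mp['snp_id'][j]!r} has >2 allele codes: {codes}"
            )
        if not codes:
            codes = ["A", "B"]  # fully missing marker: placeholder alleles
        a1 = codes[0]
        a2 = codes[1] if len(codes) == 2 else codes[0]
        both_called = called.all(axis=1)
        genotypes[both_called, j] = (col[both_called] == a1).sum(axis=1)
        a1_codes.append(a1)
        a2_codes.append(a2)

    markers = mp.assign(allele1=a1_codes, allele2=a2_codes)
    samples = pd.DataFrame({"sample_id": sample_ids, "population": populations})
    if samples["sample_id"].duplicated().any():
        # fall back to FID_IID to keep ids unique
        samples["sample_id"] = samples["population"] + "_" + samples["sample_id"]
    return GenotypeDataset(genotypes, markers, samples)


def _read_binary(prefix: Path) -> GenotypeDataset:
    bim = prefix.with_suffix(".bim")
    fam = prefix.with_suffix(".fam")
    bed = prefix.with_suffix(".bed")
    for p in (bim, fam, bed):
        if not p.exists():
            raise ParseError(f"missing file: {p}")
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chromosome", "snp_id", "cm", "position_bp", "allele1", "allele2"],
        dtype={"chromosome": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["population", "sample_id", "pat", "mat", "sex", "pheno"],
        dtype={"population": str, "sample_id": str},
    )
    n, m = len(fam_df), len(bim_df)
    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ParseError(f"{bed}: bad magic bytes {raw[:3]!r} (want 6c 1b 01, SNP-major)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(body) != bytes_per_snp * m:
        raise ParseError(
            f"{bed}: {len(body)} data bytes, expected {bytes_per_snp * m} "
            f"for {n} samples x {m} SNPs"
        )
    decoded = _BYTE_LUT[body.reshape(m, bytes_per_snp)].reshape(m, bytes_per_snp * 4)
    genotypes = np.ascontiguousarray(decoded[:, :n].T)

    markers = bim_df[["chromosome", "snp_id", "position_bp", "allele1", "allele2"]].copy()
    markers["position_bp"] = markers["position_bp"].astype(np.int64)
    samples = fam_df[["sample_id", "population"]].copy()
    return GenotypeDataset(genotypes, markers, samples)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_plink(ds: GenotypeDataset, path_prefix: str | Path, format: str = "binary") -> list[Path]:
    """Write a dataset as a PLINK fileset; returns the paths written."""
    if ds.n_samples == 0 or ds.n_markers == 0:
        raise ValueError("refusing to write an empty dataset")
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "text":
        return _write_text(ds, prefix)
    if format == "binary":
        return _write_binary(ds, prefix)
    raise ValueError(f"unknown PLINK format {format!r}")


def _marker_alleles(ds: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    a1 = ds.markers.get("allele1", pd.Series(["A"] * ds.n_markers)).astype(str).to_numpy()
    a2 = ds.markers.get("allele2", pd.Series(["B"] * ds.n_markers)).astype(str).to_numpy()
    return a1, a2


def _write_text(ds: GenotypeDataset, prefix: Path) -> list[Path]:
    mp = prefix.with_suffix(".map")
    with mp.open("w") as fh:
        for row in ds.markers.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}\n")
    a1, a2 = _marker_alleles(ds)
    ped = prefix.with_suffix(".ped")
    with ped.open("w") as fh:
        for i, srow in enumerate(ds.samples.itertuples(index=False)):
            g = ds.genotypes[i]
            pairs = np.empty((ds.n_markers, 2), dtype=object)
            pairs[g == 2] = np.stack([a1[g == 2], a1[g == 2]], axis=1)
            pairs[g == 1] = np.stack([a1[g == 1], a2[g == 1]], axis=1)
            pairs[g == 0] = np.stack([a2[g == 0], a2[g == 0]], axis=1)
            pairs[g == MISSING] = "0"
            fields = [str(srow.population), str(srow.sample_id), "0", "0", "0", "-9"]
            fields += pairs.ravel().tolist()
            fh.write(" ".join(fields) + "\n")
    return [ped, mp]


def _write_binary(ds: GenotypeDataset, prefix: Path) -> list[Path]:
    bim = prefix.with_suffix(".bim")
    fam = prefix.with_suffix(".fam")
    bed = prefix.with_suffix(".bed")
    a1, a2 = _marker_alleles(ds)
    with bim.open("w") as fh:
        for j, row in enumerate(ds.markers.itertuples(index=False)):
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position_bp}\t{a1[j]}\t{a2[j]}\n")
    with fam.open("w") as fh:
        for srow in ds.samples.itertuples(index=False):
            fh.write(f"{srow.population} {srow.sample_id} 0 0 0 -9\n")
    n, m = ds.n_samples, ds.n_markers
    bytes_per_snp = (n + 3) // 4
    code = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    gt = ds.genotypes.T  # SNP-major
    for dosage, c in _DOSAGE_TO_BED_CODE.items():
        code[:, :n][gt == dosage] = c
    packed = (
        code.reshape(m, bytes_per_snp, 4)
        * np.array([1, 4, 16, 64], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8)
    with bed.open("wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    return [bed, bim, fam]


# ---------------------------------------------------------------------------
# recoding / merging
# ---------------------------------------------------------------------------

def _sort_dataset(ds: GenotypeDataset) -> GenotypeDataset:
    srt = sort_markers(ds.markers.reset_index())
    order = srt["index"].to_numpy()
    return GenotypeDataset(
        ds.genotypes[:, order], srt.drop(columns="index"), ds.samples
    )


def recode_to_minor(ds: GenotypeDataset) -> GenotypeDataset:
    """Flip dosages (and allele columns) so allele1 is the dataset minor allele.

    Ties at frequency exactly 0.5 are broken lexicographically (the smaller
    allele code is counted), so the coding is a deterministic function of the
    genotype data alone; markers with no calls are left as loaded.
    """
    g = ds.genotypes.copy()
    nonmiss = g != MISSING
    n_called = nonmiss.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(
            n_called > 0,
            np.where(nonmiss, g, 0).sum(axis=0) / np.maximum(2 * n_called, 1),
            0.0,
        )
    flip = freq > 0.5
    if "allele1" in ds.markers.columns:
        a1s = ds.markers["allele1"].astype(str).to_numpy()
        a2s = ds.markers["allele2"].astype(str).to_numpy()
        flip = flip | ((freq == 0.5) & (a1s > a2s))
    if flip.any():
        cols = np.flatnonzero(flip)
        sub = g[:, cols]
        sub[sub != MISSING] = 2 - sub[sub != MISSING]
        g[:, cols] = sub
    markers = ds.markers.copy()
    if "allele1" in markers.columns and flip.any():
        a1 = markers["allele1"].to_numpy().copy()
        a2 = markers["allele2"].to_numpy().copy()
        a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
        markers["allele1"], markers["allele2"] = a1, a2
    return GenotypeDataset(g, markers, ds.samples)


def intersect_datasets(
    datasets: Sequence[GenotypeDataset],
    reference_map: pd.DataFrame | None = None,
) -> GenotypeDataset:
    """Stack sample batches restricted to their common SNPs.

    Positions are harmonized to ``reference_map`` (columns ``snp_id``,
    ``chromosome``, ``position_bp``) when given; otherwise all batches must
    agree on the (chromosome, position) of every shared SNP.

    Raises
    ------
    ParseError
        On an empty intersection, or conflicting positions without a
        reference map.
    """
    if len(datasets) == 0:
        raise ValueError("need at least one dataset")
    if len(datasets) == 1 and reference_map is None:
        return datasets[0]

    common = set(datasets[0].markers["snp_id"])
    for d in datasets[1:]:
        common &= set(d.markers["snp_id"])
    if not common:
        raise ParseError("no SNPs shared across all batches")

    if reference_map is not None:
        ref = reference_map.set_index("snp_id")[["chromosome", "position_bp"]]
        common &= set(ref.index)
        if not common:
            raise ParseError("no shared SNPs present in the reference map")
    else:
        ref = datasets[0].markers.set_index("snp_id")[["chromosome", "position_bp"]]
        for d in datasets[1:]:
            other = d.markers.set_index("snp_id")[["chromosome", "position_bp"]]
            both = other.loc[sorted(common)]
            mine = ref.loc[sorted(common)]
            conflict = (both["chromosome"].astype(str).to_numpy() != mine["chromosome"].astype(str).to_numpy()) | (
                both["position_bp"].to_numpy() != mine["position_bp"].to_numpy()
            )
            if conflict.any():
                bad = np.array(sorted(common))[conflict][:5]
                raise ParseError(
                    f"conflicting positions for shared SNPs (e.g. {bad.tolist()}); "
                    "supply a reference map to harmonize"
                )

    kept = sorted(common)
    markers = ref.loc[kept].reset_index()
    markers["chromosome"] = markers["chromosome"].astype(str)
    markers = sort_markers(markers[["chromosome", "position_bp", "snp_id"]])
    order_ids = markers["snp_id"].to_numpy()

    first_mk = datasets[0].markers.set_index("snp_id")
    have_alleles = all("allele1" in d.markers.columns for d in datasets)
    blocks, sample_frames = [], []
    for d in datasets:
        idx = pd.Index(d.markers["snp_id"])
        take = idx.get_indexer(order_ids)
        block = d.genotypes[:, take]
        if have_alleles and d is not datasets[0]:
            # orient each batch's dosage to the first batch's counted allele
            mk = d.markers.iloc[take].set_index("snp_id")
            ra1 = first_mk.loc[order_ids, "allele1"].astype(str).to_numpy()
            ra2 = first_mk.loc[order_ids, "allele2"].astype(str).to_numpy()
            da1 = mk["allele1"].astype(str).to_numpy()
            da2 = mk["allele2"].astype(str).to_numpy()
            same = (da1 == ra1) | (da1 == da2)  # aligned or monomorphic
            flipped = (da1 == ra2) & (da2 == ra1)
            bad = ~(same | flipped)
            if bad.any():
                raise ParseError(
                    f"incompatible allele codes across batches for SNPs "
                    f"{np.asarray(order_ids)[bad][:5].tolist()}"
                )
            cols = np.flatnonzero(flipped & ~same)
            if cols.size:
                block = block.copy()
                sub = block[:, cols]
                sub[sub != MISSING] = 2 - sub[sub != MISSING]
                block[:, cols] = sub
        blocks.append(block)
        sample_frames.append(d.samples[["sample_id", "population"]])
    genotypes = np.vstack(blocks)
    samples = pd.concat(sample_frames, ignore_index=True)
    if samples["sample_id"].duplicated().any():
        raise ParseError("duplicate sample_ids across batches")
    # allele letters follow the first batch; dosage is recoded to the minor
    # allele of the merged dataset
    first = datasets[0].markers.set_index("snp_id")
    if "allele1" in first.columns:
        markers["allele1"] = first.loc[markers["snp_id"], "allele1"].to_numpy()
        markers["allele2"] = first.loc[markers["snp_id"], "allele2"].to_numpy()
    else:
        markers = markers.assign(allele1="A", allele2="B")
    merged = GenotypeDataset(genotypes, markers, samples)
    return recode_to_minor(merged)


# ---------------------------------------------------------------------------
# quality control
# ---------------------------------------------------------------------------

def apply_qc(
    ds: GenotypeDataset,
    sample_call_rate: float = 0.9,
    snp_call_rate: float = 0.95,
    autosomes: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Quality-filter a dataset, PLINK-workflow order.

    Filter order (fixed): (1) drop non-autosomal markers and *all* markers
    sharing an exact (chromosome, position); (2) drop markers with call rate
    below ``snp_call_rate``; (3) drop samples with call rate below
    ``sample_call_rate`` over the surviving markers.

    Raises
    ------
    QCError
        If every marker or every sample is removed.
    """
    if not (0 <= sample_call_rate <= 1 and 0 <= snp_call_rate <= 1):
        raise ValueError("call-rate thresholds must lie in [0, 1]")
    auto = set(map(str, autosomes)) if autosomes is not None else set(OVINE_AUTOSOMES)

    chrom = ds.markers["chromosome"].astype(str)
    on_autosome = chrom.isin(auto).to_numpy()
    dup = ds.markers.duplicated(subset=["chromosome", "position_bp"], keep=False).to_numpy()
    keep_m = on_autosome & ~dup
    n_drop_auto = int((~on_autosome).sum())
    n_drop_dup = int((on_autosome & dup).sum())
    if not keep_m.any():
        raise QCError(
            f"all {ds.n_markers} markers removed "
            f"({n_drop_auto} non-autosomal, {n_drop_dup} duplicate-position)"
        )
    ds = ds.subset(marker_idx=np.flatnonzero(keep_m))

    called = ds.genotypes != MISSING
    snp_cr = called.mean(axis=0)
    keep_m2 = snp_cr >= snp_call_rate
    if not keep_m2.any():
        raise QCError(f"all markers removed by SNP call rate < {snp_call_rate}")
    ds = ds.subset(marker_idx=np.flatnonzero(keep_m2))

    called = ds.genotypes != MISSING
    sample_cr = called.mean(axis=1)
    keep_s = sample_cr >= sample_call_rate
    if not keep_s.any():
        raise QCError(f"all samples removed by sample call rate < {sample_call_rate}")
    ds = ds.subset(sample_idx=np.flatnonzero(keep_s))

    logger.info(
        "QC: removed %d non-autosomal, %d duplicate-position, %d low-call-rate markers; "
        "%d low-call-rate samples; kept %d samples x %d markers",
        n_drop_auto, n_drop_dup, int((~keep_m2).sum()), int((~keep_s).sum()),
        ds.n_samples, ds.n_markers,
    )
    return ds


class QCFilter(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer wrapping :func:`apply_qc`.

    Parameters mirror the function; after :meth:`transform` the attributes
    ``n_samples_kept_`` and ``n_markers_kept_`` record the surviving counts.
    """

    def __init__(
        self,
        sample_call_rate: float = 0.9,
        snp_call_rate: float = 0.95,
        autosomes: Sequence[str] | None = None,
    ):
        self.sample_call_rate = sample_call_rate
        self.snp_call_rate = snp_call_rate
        self.autosomes = autosomes

    def fit(self, X: GenotypeDataset, y=None) -> "QCFilter":
        if not isinstance(X, GenotypeDataset):
            raise TypeError("QCFilter expects a GenotypeDataset")
        return self

    def transform(self, X: GenotypeDataset) -> GenotypeDataset:
        out = apply_qc(
            X,
            sample_call_rate=self.sample_call_rate,
            snp_call_rate=self.snp_call_rate,
            autosomes=self.autosomes,
        )
        self.n_samples_kept_ = out.n_samples
        self.n_markers_kept_ = out.n_markers
        return out
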