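"""Gene/QTL annotation of ROH islands and QTL trait enrichment.

Genes come from an Ensembl GTF or GFF3 (gene-level features only); QTLs from
the Animal-QTLdb GFF dialect or a minimal TSV.  A feature is associated with
an island when its interval intersects the island extended by a flanking
window (500 kb upstream and downstream by default).

Trait enrichment uses the one-sided hypergeometric test: drawing the observed
number of trait QTLs among the island-associated QTLs, from a database
containing that trait's total, with Benjamini-Hochberg adjustment across
traits.  The richness factor of a trait is observed hits / database total for
that trait.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

GENE_COLUMNS = ("gene_id", "gene_name", "chromosome", "start_bp", "end_bp",
                "biotype", "length_bp")
QTL_COLUMNS = ("qtl_id", "trait", "qtl_type", "chromosome", "start_bp", "end_bp")

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')
_GFF3_ATTR = re.compile(r'([^;=]+)=("?)([^;"]*)\2')


def gene_length(start_bp: int, end_bp: int) -> int:
    """Gene length convention: 1-based inclusive, ``end - start + 1``."""
    if end_bp < start_bp:
        raise ValueError("gene end must be >= start")
    return int(end_bp - start_bp + 1)


def _parse_attributes(attr: str) -> dict[str, str]:
    if "=" in attr.split(";", 1)[0]:
        pairs = _GFF3_ATTR.findall(attr)
        return {k.strip(): v.strip().strip('"') for k, v, *_ in
                [(m[0], m[2]) for m in pairs]}
    return dict(_GTF_ATTR.findall(attr))


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    """Read gene-level records from a GTF or GFF3 file.

    Only lines whose feature type is ``gene`` are kept.  Lines with a
    malformed attribute column are skipped with a warning.  Chromosome names
    are normalized by stripping a leading ``chr``.
    """
    rows = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            logger.warning("%s:%d: fewer than 9 columns; skipped", path, ln)
            continue
        seqname, _source, feature, start, end = parts[0], parts[1], parts[2], parts[3], parts[4]
        if feature != "gene":
            continue
        try:
            attrs = _parse_attributes(parts[8])
            start_bp, end_bp = int(start), int(end)
        except (ValueError, AttributeError):
            logger.warning("%s:%d: malformed gene line skipped", path, ln)
            continue
        gene_id = attrs.get("gene_id") or attrs.get("ID", "")
        if gene_id.startswith("gene:"):
            gene_id = gene_id[5:]
        if not gene_id:
            logger.warning("%s:%d: gene without an id skipped", path, ln)
            continue
        rows.append(
            (
                gene_id,
                attrs.get("gene_name") or attrs.get("Name", gene_id),
                re.sub(r"^chr", "", seqname),
                start_bp,
                end_bp,
                attrs.get("gene_biotype") or attrs.get("biotype", ""),
                gene_length(start_bp, end_bp),
            )
        )
    return pd.DataFrame(rows, columns=list(GENE_COLUMNS))


def read_qtl_database(path: str | Path) -> pd.DataFrame:
    """Read QTL records from an Animal-QTLdb GFF download or a minimal TSV.

    The GFF dialect carries ``QTL_ID``, ``Name`` (trait) and ``trait_type``
    in the attribute column.  The TSV fallback needs a header with columns
    ``qtl_id``, ``trait``, ``chromosome``, ``start_bp``, ``end_bp`` and
    optionally ``qtl_type``.
    """
    path = Path(path)
    first = ""
    for line in path.read_text().splitlines():
        if line.strip() and not line.startswith("#"):
            first = line
            break
    if "\t" in first and len(first.split("\t")) >= 9:
        return _read_qtl_gff(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"qtl_id", "trait", "chromosome", "start_bp", "end_bp"} - set(df.columns)
    if missing:
        raise ValueError(f"QTL TSV lacks columns: {sorted(missing)}")
    if "qtl_type" not in df.columns:
        df["qtl_type"] = ""
    df["chromosome"] = df["chromosome"].astype(str)
    return df[list(QTL_COLUMNS)]


def _read_qtl_gff(path: Path) -> pd.DataFrame:
    rows = []
    for ln, line in enumerate(path.read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 9:
            logger.warning("%s:%d: fewer than 9 columns; skipped", path, ln)
            continue
        seqname, start, end, attr = parts[0], parts[3], parts[4], parts[8]
        try:
            attrs = _parse_attributes(attr)
            start_bp, end_bp = int(float(start)), int(float(end))
        except ValueError:
            logger.warning("%s:%d: malformed QTL line skipped", path, ln)
            continue
        qtl_id = attrs.get("QTL_ID", f"QTL_{ln}")
        rows.append(
            (
                qtl_id,
                attrs.get("Name", attrs.get("trait", "")),
                attrs.get("trait_type", ""),
                re.sub(r"^[Cc]hr\.?", "", seqname),
                start_bp,
                end_bp,
            )
        )
    return pd.DataFrame(rows, columns=list(QTL_COLUMNS))


def features_in_islands(
    islands: pd.DataFrame, features: pd.DataFrame, flank_bp: int = 500_000
) -> pd.DataFrame:
    """Features whose interval intersects an island extended by ``flank_bp``.

    Both inputs carry ``chromosome``, ``start_bp``, ``end_bp``; every feature
    column is preserved in the output next to ``island_chromosome``,
    ``island_start_bp`` and ``island_end_bp``.  Returns an empty table when
    nothing overlaps.
    """
    hits = []
    for isl in islands.itertuples(index=False):
        lo = isl.start_bp - flank_bp
        hi = isl.end_bp + flank_bp
        same = features.loc[
            (features["chromosome"].astype(str) == str(isl.chromosome))
            & (features["end_bp"] >= lo)
            & (features["start_bp"] <= hi)
        ]
        for _, feat in same.iterrows():
            row = {
                "island_chromosome": str(isl.chromosome),
                "island_start_bp": int(isl.start_bp),
                "island_end_bp": int(isl.end_bp),
            }
            row.update(feat.to_dict())
            hits.append(row)
    if not hits:
        cols = ["island_chromosome", "island_start_bp", "island_end_bp"]
        return pd.DataFrame(columns=cols + list(features.columns))
    return pd.DataFrame(hits)


def qtl_enrichment(hits: pd.DataFrame, database: pd.DataFrame,
                   by: str = "trait") -> pd.DataFrame:
    """Per-trait hypergeometric enrichment of island-associated QTLs.

    Parameters
    ----------
    hits
        Output of :func:`features_in_islands` on QTL records (must carry
        ``qtl_id`` and the ``by`` column).
    database
        Full QTL table the hits were drawn from.
    by
        Grouping column: ``"trait"`` (default) or ``"qtl_type"``.

    Returns
    -------
    DataFrame with one row per trait present among the hits: ``trait``,
    ``n_observed``, ``n_trait_total``, ``richness_factor``, ``p_value``
    (upper-tail hypergeometric) and ``adjusted_p`` (Benjamini-Hochberg).
    """
    if database.empty:
        raise ValueError("QTL database is empty")
    if hits.empty:
        return pd.DataFrame(
            columns=["trait", "n_observed", "n_trait_total", "richness_factor",
                     "p_value", "adjusted_p"]
        )
    hit_ids = hits["qtl_id"].drop_duplicates()
    drawn = database.loc[database["qtl_id"].isin(hit_ids)]
    n_drawn = int(drawn["qtl_id"].nunique())
    n_total = int(database["qtl_id"].nunique())

    rows = []
    for trait, grp in drawn.groupby(by, sort=True):
        k = int(grp["qtl_id"].nunique())
        big_k = int(database.loc[database[by] == trait, "qtl_id"].nunique())
        if big_k == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, n_total, big_k, n_drawn))
        rows.append((trait, k, big_k, k / big_k, p))
    out = pd.DataFrame(
        rows, columns=["trait", "n_observed", "n_trait_total",
                       "richness_factor", "p_value"]
    )
    out["adjusted_p"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)
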