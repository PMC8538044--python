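"""Pooled insertional-mutagenesis (REMI-Seq) selection analysis.

Raw insertion read counts are normalized per sample (tags at one insertion
point summed, then scaled to reads per million). Mutants are binned by
their mean normalized vehicle (DMSO) counts — <100 reads, 100-1000 reads
(inclusive), >1000 reads — so that mutants with similar depths are
compared. Per replicate, the log2 fold change of each mutant against the
DMSO replicate mean is standardized within its (bin, replicate) to a
Z-score. Advantaged mutants have Z > 1.5 in both replicates at round 5;
disadvantaged mutants have Z < -1 in both replicates at round 2, with the
<100-read bin excluded because its stochastic dropout rate is high.

Selected insertions map to genes (intragenic, or intergenic within 500 bp
upstream of a transcription start, strand-aware); insertions in tRNAs,
pseudogenes or transposable elements, and genes on a growth-mutant
blacklist, are removed. Gene lists are compared by upper-tail
hypergeometric overlap, rank-quartile chi-squared tests, and GO-term
over-representation against the screened universe.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InsertionAnnotation",
    "EnrichmentResult",
    "BINS",
    "normalize_counts",
    "bin_mutants",
    "compute_lfc_z",
    "select_mutants",
    "annotate_insertions",
    "assign_genes",
    "overlap_test",
    "rank_quartile_test",
    "go_enrichment",
]

logger = logging.getLogger(__name__)

BINS = ("bin100", "bin1000", "bin10000")

#: Gene classes whose insertions are removed from gene lists.
EXCLUDED_GENE_TYPES = ("tRNA", "pseudogene", "transposable_element")

SAMPLE_KEYS = ["screen", "replicate", "round"]


@dataclass(frozen=True)
class InsertionAnnotation:
    insertion_id: str
    chromosome: str
    position: int
    category: str  # intragenic | promoter_within_500bp | intergenic
    assigned_gene: str | None = None
    excluded_class: str = "none"  # none | tRNA | pseudogene | transposable_element


@dataclass(frozen=True)
class EnrichmentResult:
    label: str
    k: int  # overlap count
    K: int  # list size
    n: int  # annotated in universe
    N: int  # universe size
    p: float

    def __post_init__(self) -> None:
        if self.k > min(self.K, self.n):
            raise ValueError("overlap exceeds list or annotation size")


def normalize_counts(raw: pd.DataFrame, scale: float = 1e6) -> pd.DataFrame:
    """Normalize raw tag counts to reads-per-million per sample.

    ``raw`` is a long table ``insertion_id, screen, replicate, round,
    count`` with an optional ``tag`` column (multiple sequence tags of one
    insertion point are summed first) and an optional boolean ``unique``
    column (non-uniquely mapped rows are dropped before scaling).
    Duplicate (insertion, sample) rows without a tag column are rejected.

    Returns a wide matrix: index insertion_id, MultiIndex columns
    (screen, replicate, round), missing combinations filled with 0.
    """
    required = {"insertion_id", "count", *SAMPLE_KEYS}
    if not required <= set(raw.columns):
        raise ValueError(f"count table needs columns {sorted(required)}")
    df = raw
    if "unique" in df.columns:
        df = df[df["unique"].astype(bool)]
    if "tag" in df.columns:
        df = df.groupby(["insertion_id", *SAMPLE_KEYS], as_index=False)["count"].sum()
    elif df.duplicated(["insertion_id", *SAMPLE_KEYS]).any():
        raise ValueError(
            "duplicate (insertion, sample) rows; supply a 'tag' column to sum tags"
        )
    if (df["count"] < 0).any():
        raise ValueError("counts must be >= 0")
    wide = df.pivot_table(
        index="insertion_id", columns=SAMPLE_KEYS, values="count", fill_value=0.0
    )
    totals = wide.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("every sample must have a positive total read count")
    return wide / totals * scale


def _dmso_mean(matrix: pd.DataFrame, round_: int, control: str = "DMSO") -> pd.Series:
    try:
        ctrl = matrix[control].xs(round_, axis=1, level="round")
    except KeyError as exc:
        raise ValueError(f"no {control} samples for round {round_}") from exc
    if ctrl.shape[1] < 2:
        raise ValueError(f"need both {control} replicates for round {round_}")
    return ctrl.mean(axis=1)


def bin_mutants(
    matrix: pd.DataFrame, round_: int, control: str = "DMSO"
) -> pd.Series:
    """Bin mutants by mean normalized control counts for one round.

    Boundaries: <100 -> bin100; 100-1000 inclusive -> bin1000;
    >1000 -> bin10000.
    """
    mean = _dmso_mean(matrix, round_, control)
    bins = pd.Series("bin1000", index=mean.index, name="bin")
    bins[mean < 100] = "bin100"
    bins[mean > 1000] = "bin10000"
    return bins


def compute_lfc_z(
    matrix: pd.DataFrame,
    screen: str,
    round_: int,
    pseudocount: float = 1.0,
    control: str = "DMSO",
) -> pd.DataFrame:
    """Per-mutant log2 fold changes vs the DMSO mean and within-bin Z-scores.

    ``lfc = log2((count + pc) / (dmso_mean + pc))`` per replicate;
    ``z = (lfc - bin mean) / bin SD`` computed within each
    (bin, replicate). Bins with fewer than 3 members get undefined (NaN)
    Z-scores with a warning; select_mutants treats them as neutral.

    Returns a DataFrame indexed by mutant with columns ``bin``,
    ``dmso_mean`` and ``lfc_<rep>``/``z_<rep>`` per replicate.
    """
    dmso_mean = _dmso_mean(matrix, round_, control)
    bins = bin_mutants(matrix, round_, control)
    try:
        scr = matrix[screen].xs(round_, axis=1, level="round")
    except KeyError as exc:
        raise ValueError(f"no {screen} samples for round {round_}") from exc
    out = pd.DataFrame({"bin": bins, "dmso_mean": dmso_mean})
    small = bins.value_counts()
    small_bins = set(small[small < 3].index)
    if small_bins:
        warnings.warn(
            f"bins with <3 members have undefined Z-scores: {sorted(small_bins)}",
            stacklevel=2,
        )
    for rep in scr.columns:
        lfc = np.log2((scr[rep] + pseudocount) / (dmso_mean + pseudocount))
        grouped = lfc.groupby(bins)
        z = (lfc - grouped.transform("mean")) / grouped.transform("std", ddof=1)
        z[bins.isin(small_bins)] = np.nan
        out[f"lfc_{rep}"] = lfc
        out[f"z_{rep}"] = z
    return out


def _z_columns(calls: pd.DataFrame) -> list[str]:
    cols = [c for c in calls.columns if c.startswith("z_")]
    if not cols:
        raise ValueError("no z_* columns; pass the output of compute_lfc_z")
    return cols


def select_mutants(
    calls_round2: pd.DataFrame,
    calls_round5: pd.DataFrame,
    z_adv: float = 1.5,
    z_dis: float = -1.0,
) -> tuple[set[str], set[str]]:
    """Select advantaged and disadvantaged mutants.

    Advantaged: Z > ``z_adv`` in every replicate at round 5. Disadvantaged:
    Z < ``z_dis`` in every replicate at round 2, excluding the <100-read
    bin. The two sets are disjoint; in the (pathological) case of a mutant
    qualifying for both, it is dropped from the disadvantaged set with a
    warning.
    """
    z5 = calls_round5[_z_columns(calls_round5)]
    advantaged = set(z5.index[(z5 > z_adv).all(axis=1)])
    z2 = calls_round2[_z_columns(calls_round2)]
    dis_mask = (z2 < z_dis).all(axis=1) & (calls_round2["bin"] != "bin100")
    disadvantaged = set(z2.index[dis_mask])
    both = advantaged & disadvantaged
    if both:
        logger.warning("mutants in both sets dropped from disadvantaged: %s", sorted(both))
        disadvantaged -= both
    return advantaged, disadvantaged


def annotate_insertions(
    insertions: pd.DataFrame,
    genes: pd.DataFrame,
    promoter_window_bp: int = 500,
) -> pd.DataFrame:
    """Assign insertion points to genes.

    ``insertions``: columns ``insertion_id, chromosome, position`` (1-based).
    ``genes``: columns ``gene_id, chromosome, start, end, strand,
    gene_type`` (1-based inclusive; strand ``+``/``-``).

    An insertion inside a gene body is intragenic (nearest transcription
    start wins if bodies overlap). Otherwise, an insertion within
    ``promoter_window_bp`` upstream of a start — upstream being
    strand-aware — is a promoter insertion assigned to that gene, the
    nearer start winning between two divergent genes (logged). Anything
    else is intergenic and unassigned. The excluded class records whether
    the assigned gene is a tRNA/pseudogene/transposable element.
    """
    req_i = {"insertion_id", "chromosome", "position"}
    req_g = {"gene_id", "chromosome", "start", "end", "strand", "gene_type"}
    if not req_i <= set(insertions.columns):
        raise ValueError(f"insertion table needs columns {sorted(req_i)}")
    if not req_g <= set(genes.columns):
        raise ValueError(f"gene table needs columns {sorted(req_g)}")
    if not genes["strand"].isin(["+", "-"]).all():
        raise ValueError("gene strand must be + or -")

    # chromosome labels may arrive as ints from one table and strings from
    # the other; compare them as strings
    insertions = insertions.assign(chromosome=insertions["chromosome"].astype(str))
    genes = genes.assign(chromosome=genes["chromosome"].astype(str))
    by_chrom = {chrom: g for chrom, g in genes.groupby("chromosome")}
    rows = []
    for rec in insertions.itertuples(index=False):
        pos = int(rec.position)
        g = by_chrom.get(rec.chromosome)
        category, gene, excluded = "intergenic", None, "none"
        if g is not None:
            inside = g[(g["start"] <= pos) & (pos <= g["end"])]
            if len(inside):
                tss = np.where(inside["strand"] == "+", inside["start"], inside["end"])
                hit = inside.iloc[int(np.argmin(np.abs(tss - pos)))]
                category, gene = "intragenic", hit["gene_id"]
                excluded = hit["gene_type"] if hit["gene_type"] in EXCLUDED_GENE_TYPES else "none"
            else:
                tss = np.where(g["strand"] == "+", g["start"], g["end"])
                upstream_dist = np.where(g["strand"] == "+", tss - pos, pos - tss)
                ok = (upstream_dist >= 1) & (upstream_dist <= promoter_window_bp)
                if ok.any():
                    cand = g[ok]
                    dists = upstream_dist[ok]
                    if len(cand) > 1:
                        logger.info(
                            "insertion %s upstream of %d genes; assigning the nearest start",
                            rec.insertion_id,
                            len(cand),
                        )
                    hit = cand.iloc[int(np.argmin(dists))]
                    category, gene = "promoter_within_500bp", hit["gene_id"]
                    excluded = (
                        hit["gene_type"] if hit["gene_type"] in EXCLUDED_GENE_TYPES else "none"
                    )
        rows.append(
            {
                "insertion_id": rec.insertion_id,
                "chromosome": rec.chromosome,
                "position": pos,
                "category": category,
                "assigned_gene": gene,
                "excluded_class": excluded,
            }
        )
    return pd.DataFrame(rows).set_index("insertion_id")


def assign_genes(
    mutants: Iterable[str],
    annotations: pd.DataFrame,
    blacklist: Iterable[str] = (),
) -> list[str]:
    """Turn a selected-mutant set into a gene list.

    Intragenic and promoter (<500 bp upstream) insertions contribute their
    assigned gene; insertions in tRNAs/pseudogenes/transposable elements
    and genes on the blacklist are removed; other intergenic insertions are
    dropped (they stay in the mutant-level output upstream). Unknown mutant
    ids raise.
    """
    blacklist = set(blacklist)
    genes: set[str] = set()
    for m in mutants:
        if m not in annotations.index:
            raise KeyError(f"mutant {m!r} missing from the annotation table")
        rec = annotations.loc[m]
        if rec["excluded_class"] != "none":
            continue
        gene = rec["assigned_gene"]
        if gene is None or (isinstance(gene, float) and np.isnan(gene)):
            continue
        if gene in blacklist:
            continue
        genes.add(gene)
    return sorted(genes)


def overlap_test(
    list_a: Iterable[str], list_b: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric probability of the observed overlap.

    P(X >= |A∩B|) drawing |A| genes from a universe of which |B| are
    marked. Both lists must be subsets of the universe.
    """
    universe = set(universe)
    a, b = set(list_a), set(list_b)
    if not a <= universe or not b <= universe:
        raise ValueError("gene lists must be subsets of the universe")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(b), len(a)))
    return EnrichmentResult("overlap", k, len(a), len(b), len(universe), min(p, 1.0))


def rank_quartile_test(
    scores: pd.Series, listed: Iterable[str]
) -> tuple[dict[str, int], float, float]:
    """Quartile placement of listed mutants within a ranked screen.

    All scored mutants are ranked by ``scores`` ascending (Q1 = most
    decreased, Q4 = most increased; ties broken by stable mutant-id order)
    and split into quartiles whose sizes differ by at most 1. The listed
    mutants' quartile counts are tested against uniform n/4 by a
    chi-squared goodness-of-fit test (3 df).

    Returns (per-quartile counts, chi2, p).
    """
    listed = list(listed)
    missing = [m for m in listed if m not in scores.index]
    if missing:
        raise ValueError(f"listed mutants not scored: {missing[:5]}")
    order = scores.sort_index(kind="stable").sort_values(kind="stable").index
    n = len(order)
    sizes = [n // 4 + (1 if i < n % 4 else 0) for i in range(4)]
    quartile = {}
    start = 0
    for qi, size in enumerate(sizes, start=1):
        for m in order[start : start + size]:
            quartile[m] = f"Q{qi}"
        start += size
    counts = {f"Q{i}": 0 for i in range(1, 5)}
    for m in listed:
        counts[quartile[m]] += 1
    observed = np.array([counts[q] for q in ("Q1", "Q2", "Q3", "Q4")], dtype=float)
    chi2, p = stats.chisquare(observed)
    return counts, float(chi2), float(p)


def go_enrichment(
    gene_list: Iterable[str],
    universe: Iterable[str],
    term_to_genes: Mapping[str, Iterable[str]] | pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric GO-term over-representation against the universe.

    ``term_to_genes`` maps term -> annotated genes, or is a two-column
    DataFrame ``term, gene``. Annotations are intersected with the
    universe; terms annotating no universe gene are skipped. Terms with
    p < ``alpha`` are returned sorted by ascending p. No multiplicity
    correction by default; ``bh_correct=True`` applies Benjamini-Hochberg
    and filters on the adjusted values instead.
    """
    universe = set(universe)
    genes = set(gene_list)
    if not genes <= universe:
        raise ValueError("gene list must be a subset of the universe")
    if isinstance(term_to_genes, pd.DataFrame):
        term_to_genes = {
            term: set(sub["gene"]) for term, sub in term_to_genes.groupby("term")
        }
    results = []
    for term, annotated in term_to_genes.items():
        ann = set(annotated) & universe
        if not ann:
            continue
        k = len(genes & ann)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(ann), len(genes)))
        results.append(EnrichmentResult(term, k, len(genes), len(ann), len(universe), min(p, 1.0)))
    if bh_correct and results:
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, _, _ = multipletests(
            [r.p for r in results], alpha=alpha, method="fdr_bh"
        )
        kept = [
            EnrichmentResult(r.label, r.k, r.K, r.n, r.N, float(pa))
            for r, pa, rej in zip(results, p_adj, reject)
            if rej
        ]
    else:
        kept = [r for r in results if r.p < alpha]
    return sorted(kept, key=lambda r: (r.p, r.label))
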