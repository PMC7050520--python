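"""Poly(A) tail statistics coupled to transcript structure.

Joins per-read tail-length estimates (the tab-separated dialect written by
signal-level tail estimators: readname ... polya_length, qc_tag) to the
isoform, UTR, PAS and intron-retention labels produced by the pipeline,
then reproduces the study-level analyses: tail-vs-expression and
tail-vs-UTR-length regressions, distribution comparisons, PAS-usage
chi-square, splice/UTR coupling by Fisher's exact test with
Benjamini-Hochberg correction, saturation subsampling, metagene coverage,
and the pairing of splice and UTR isoforms into full-length isoforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

NANOPOLISH_COLUMNS = (
    "readname", "contig", "position", "leader_start", "adapter_start",
    "polya_start", "transcript_start", "read_rate", "polya_length", "qc_tag",
)


def load_polya_table(path) -> pd.DataFrame:
    """Read a per-read tail-length table (TSV).

    Accepts a headered table with at least readname / polya_length / qc_tag
    columns, or a headerless table in the standard signal-estimator column
    order.  Duplicate read names are an error.
    """
    first = pd.read_csv(path, sep="\t", nrows=1)
    if "readname" in first.columns:
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t", header=None,
                         names=NANOPOLISH_COLUMNS[: len(first.columns)])
    if df["readname"].duplicated().any():
        dup = df.loc[df["readname"].duplicated(), "readname"].iloc[0]
        raise ValueError(f"duplicate read id in poly(A) table: {dup}")
    df["polya_length"] = pd.to_numeric(df["polya_length"], errors="coerce")
    return df[["readname", "polya_length", "qc_tag"]]


def polya_qc_map(table: pd.DataFrame) -> dict:
    return dict(zip(table["readname"], table["qc_tag"]))


def build_records(table: pd.DataFrame, outcomes, iso_calls=None,
                  utr_calls=None, utr_assignment=None) -> pd.DataFrame:
    """Per-read records joining tails to structure labels.

    Only QC-PASS tail estimates are retained.  Reads kept by the filter
    (full-length passing or diverted intron-retention) receive gene,
    isoform, UTR, PAS-type, UTR-length and retention labels where defined.
    """
    tails = table[table["qc_tag"] == "PASS"].set_index("readname")["polya_length"]
    iso_by_read: dict = {}
    for c in iso_calls or []:
        for r in c.read_ids:
            iso_by_read[r] = c.isoform_id
    utr_by_id = {c.utr_id: c for c in (utr_calls or [])}
    rows = []
    for o in outcomes:
        if o.stage_reached not in ("PASS", "INTRON_RETENTION"):
            continue
        if o.read_id not in tails.index:
            continue
        utr_id = (utr_assignment or {}).get(o.read_id)
        uc = utr_by_id.get(utr_id)
        rows.append(
            {
                "read_id": o.read_id,
                "tail_length": float(tails.loc[o.read_id]),
                "gene": o.gene_id,
                "isoform_id": iso_by_read.get(o.read_id),
                "utr_id": utr_id,
                "pas_type": uc.pas.pas_type if uc and uc.pas else None,
                "utr_length": uc.utr_length_spliced if uc else None,
                "intron_retained": o.intron_retained,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "read_id", "tail_length", "gene", "isoform_id", "utr_id",
            "pas_type", "utr_length", "intron_retained",
        ],
    )


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    slope_se: float
    intercept_se: float


def _ols(x, y) -> RegressionResult:
    if len(x) < 2:
        raise ValueError("need at least 2 points for a regression")
    X = sm.add_constant(np.asarray(x, dtype=float))
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        n=len(x),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
    )


def tail_vs_expression(records: pd.DataFrame, min_reads: int = 10
                       ) -> RegressionResult:
    """Median tail length per isoform regressed on log10 supporting reads.

    Isoforms with fewer than `min_reads` QC-PASS tail records are excluded;
    the supporting-read count doubles as the expression proxy.
    """
    df = records.dropna(subset=["isoform_id", "tail_length"])
    g = df.groupby("isoform_id")["tail_length"].agg(["median", "count"])
    g = g[g["count"] >= min_reads]
    if len(g) < 2:
        raise ValueError("fewer than 2 isoforms meet the read threshold")
    return _ols(np.log10(g["count"]), g["median"])


def tail_vs_utr_length(records: pd.DataFrame, min_reads: int = 10
                       ) -> RegressionResult:
    """Median tail length per 3'-UTR isoform regressed on log10 UTR length."""
    df = records.dropna(subset=["utr_id", "tail_length", "utr_length"])
    df = df[df["utr_length"] > 0]
    g = df.groupby("utr_id").agg(
        median=("tail_length", "median"),
        count=("tail_length", "count"),
        utr_length=("utr_length", "first"),
    )
    g = g[g["count"] >= min_reads]
    if len(g) < 2:
        raise ValueError("fewer than 2 UTRs meet the read threshold")
    return _ols(np.log10(g["utr_length"]), g["median"])


def compare_distributions(a, b) -> dict:
    """Two-sided KS and Mann-Whitney U comparisons of two tail samples.

    The U test uses exact enumeration for small tie-free samples (both
    n <= 20) and the tie-corrected normal approximation otherwise.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    ks = stats.ks_2samp(a, b, alternative="two-sided")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
    mwu = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return {
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
        "mwu_stat": float(mwu.statistic),
        "mwu_p": float(mwu.pvalue),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }


def pas_usage_chi2(counts) -> dict:
    """Pearson chi-square on a condition x PAS-type count table.

    Zero-margin rows/columns are dropped with a warning; dof is
    (r-1)(c-1) on the retained table.
    """
    t = np.asarray(counts, dtype=float)
    keep_rows = t.sum(axis=1) > 0
    keep_cols = t.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping zero-margin rows/columns from PAS table")
        t = t[keep_rows][:, keep_cols]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table after dropping zero margins")
    chi2, p, dof, _ = stats.chi2_contingency(t, correction=False)
    return {"chi2": float(chi2), "dof": int(dof), "p": float(p)}


def splice_utr_coupling(records: pd.DataFrame, min_isoforms: int = 2,
                        min_utrs: int = 2) -> pd.DataFrame:
    """Per-gene association between splice-isoform and 3'-UTR choice.

    Genes with at least two splice isoforms and two UTRs among the
    labelled reads are tested; the r x c read-count table is collapsed to
    2x2 (top splice isoform vs rest, top UTR vs rest) so Fisher's exact
    test stays exact, and p-values are Benjamini-Hochberg corrected across
    genes.
    """
    df = records.dropna(subset=["isoform_id", "utr_id"])
    rows = []
    for gene, sub in df.groupby("gene"):
        tab = pd.crosstab(sub["isoform_id"], sub["utr_id"])
        if tab.shape[0] < min_isoforms or tab.shape[1] < min_utrs:
            continue
        top_iso = tab.sum(axis=1).sort_values(
            ascending=False, kind="stable"
        ).index[0]
        top_utr = tab.sum(axis=0).sort_values(
            ascending=False, kind="stable"
        ).index[0]
        a = int(tab.loc[top_iso, top_utr])
        b = int(tab.loc[top_iso].sum() - a)
        c = int(tab[top_utr].sum() - a)
        d = int(tab.values.sum() - a - b - c)
        table2 = np.array([[a, b], [c, d]])
        if (table2.sum(axis=0) == 0).any() or (table2.sum(axis=1) == 0).any():
            continue
        _, p = stats.fisher_exact(table2, alternative="two-sided")
        rows.append({"gene": gene, "p": float(p), "a": a, "b": b, "c": c, "d": d})
    out = pd.DataFrame(rows, columns=["gene", "p", "a", "b", "c", "d"])
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out


def saturation_curve(read_to_isoform: dict, fractions, n_reps: int = 10,
                     seed: int = 0) -> pd.DataFrame:
    """Mean distinct-isoform count under read subsampling.

    Uniform sampling without replacement at each fraction, averaged over
    `n_reps` replicates with a seeded generator.
    """
    rng = np.random.default_rng(seed)
    reads = np.array(sorted(read_to_isoform))
    isos = np.array([read_to_isoform[r] for r in reads])
    n = len(reads)
    rows = []
    for f in fractions:
        if not (0 < f <= 1):
            raise ValueError(f"fraction outside (0, 1]: {f}")
        k = int(round(f * n))
        counts = []
        for _ in range(n_reps):
            idx = rng.choice(n, size=k, replace=False)
            counts.append(len(set(isos[idx])))
        rows.append({"fraction": f, "n_reads": k,
                     "mean_isoforms": float(np.mean(counts))})
    return pd.DataFrame(rows)


def metagene_coverage(reads, ann, bins_utr5: int = 20, bins_body: int = 60,
                      bins_utr3: int = 20) -> np.ndarray:
    """Normalized coverage across the scaled average gene, 5'->3'.

    Coverage is accumulated in spliced (exonic) coordinates of each gene's
    representative transcript (the longest), so introns do not dilute the
    profile.  The spliced transcript is partitioned by its CDS into 5'-UTR
    / body / 3'-UTR regions, each rescaled to a fixed bin count so every
    gene contributes the same shape; genes without a CDS are rescaled
    whole across all bins.  Per-bin coverage (mean depth in the bin) is
    summed over genes and the profile normalized to sum to 1.
    """
    from intervaltree import IntervalTree

    total_bins = bins_utr5 + bins_body + bins_utr3
    gene_defs = {}
    for gid, tids in ann.genes.items():
        ts = [ann.transcripts[t] for t in tids]
        rep = max(ts, key=lambda t: (t.spliced_length, t.transcript_id))
        gene_defs[gid] = rep
    trees: dict = {}
    exon_offsets: dict = {}
    cov: dict = {}
    for gid, rep in gene_defs.items():
        trees.setdefault((rep.chrom, rep.strand), IntervalTree()).addi(
            rep.start, rep.end, gid
        )
        offs, cum = [], 0
        for s, e in rep.exons:
            offs.append((s, e, cum))
            cum += e - s
        exon_offsets[gid] = offs
        cov[gid] = np.zeros(rep.spliced_length)
    for r in reads:
        tree = trees.get((r.chrom, r.strand))
        if tree is None:
            continue
        hits = {iv.data for b0, b1 in r.blocks for iv in tree.overlap(b0, b1)}
        for gid in hits:
            arr = cov[gid]
            for b0, b1 in r.blocks:
                for (es, ee, off) in exon_offsets[gid]:
                    a, b = max(b0, es), min(b1, ee)
                    if a < b:
                        arr[off + a - es:off + b - es] += 1
    profile = np.zeros(total_bins)

    def rebin(values, nbins):
        if len(values) == 0 or nbins == 0:
            return np.zeros(nbins)
        edges = np.linspace(0, len(values), nbins + 1)
        return np.array([
            values[int(np.floor(a)):max(int(np.ceil(b)), int(np.floor(a)) + 1)].mean()
            for a, b in zip(edges[:-1], edges[1:])
        ])

    def spliced_index(gid, pos):
        for (es, ee, off) in exon_offsets[gid]:
            if pos < ee:
                return off + max(0, pos - es)
        return cov[gid].shape[0]

    for gid, rep in gene_defs.items():
        arr = cov[gid]
        if rep.cds:
            cds_lo = spliced_index(gid, min(s for s, _ in rep.cds))
            cds_hi = spliced_index(gid, max(e for _, e in rep.cds) - 1) + 1
            if rep.strand == "-":
                arr = arr[::-1]
                cds_lo, cds_hi = len(arr) - cds_hi, len(arr) - cds_lo
            profile[:bins_utr5] += rebin(arr[:cds_lo], bins_utr5)
            profile[bins_utr5:bins_utr5 + bins_body] += rebin(
                arr[cds_lo:cds_hi], bins_body
            )
            profile[bins_utr5 + bins_body:] += rebin(arr[cds_hi:], bins_utr3)
        else:
            if rep.strand == "-":
                arr = arr[::-1]
            profile += rebin(arr, total_bins)
    s = profile.sum()
    return profile / s if s > 0 else profile


def full_length_pairing(iso_calls, utr_calls) -> pd.DataFrame:
    """Pair splice isoforms with 3'-UTR isoforms sharing supporting reads.

    One full-length isoform per observed (splice isoform, UTR) pair; splice
    isoforms none of whose reads were assigned to a cleavage site are kept
    as UTR-less full-length isoforms.
    """
    utr_by_read: dict = {}
    for c in utr_calls:
        for r in c.read_ids:
            utr_by_read[r] = c.utr_id
    rows = []
    for ic in iso_calls:
        shared_by_utr: dict = {}
        for r in ic.read_ids:
            u = utr_by_read.get(r)
            if u is not None:
                shared_by_utr[u] = shared_by_utr.get(u, 0) + 1
        for utr_id in sorted(shared_by_utr):
            rows.append({
                "isoform_id": ic.isoform_id, "utr_id": utr_id,
                "gene": ic.gene_id, "n_shared_reads": shared_by_utr[utr_id],
            })
        if not shared_by_utr:
            rows.append({
                "isoform_id": ic.isoform_id, "utr_id": None,
                "gene": ic.gene_id, "n_shared_reads": 0,
            })
    return pd.DataFrame(
        rows, columns=["isoform_id", "utr_id", "gene", "n_shared_reads"]
    )
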