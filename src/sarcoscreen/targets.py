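"""Differential expression and the tumor-specific-gene filter cascade.

The cascade starts from a gene x sample count matrix: CPM normalization, a
rank-based differential test (Wilcoxon rank-sum between independent groups,
signed-rank for paired designs) on log2(CPM + 1) with Benjamini-Hochberg
adjustment, then successive set filters:

* tumor-specific genes (TSG): |fold change| >= 2 (inclusive) and adjusted
  p < 0.05 (strict), split into up- and down-regulated sets;
* pan-cancer exclusion: TSGs up-regulated in any other cancer type are
  dropped, leaving the disease-specific up-regulated genes;
* functional-class annotation (kinase / epigenetic factor / transcription
  factor / metabolism / cell surface) and overlap with approved-drug targets;
* surface-target screen for adoptive cell therapy: |fold change| >= 4 and
  mean tumor CPM >= 90, both inclusive;
* single-cell percent-expressed filter: > 25% of cells in at least one cell
  type (strict), "broad" when passing in >= 5 cell types;
* pre/post-chemotherapy paired overlap and the mRNA/protein intersection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "cpm_normalize",
    "differential_expression",
    "filter_tsg",
    "PanCancerResult",
    "pan_cancer_exclude",
    "classify_functional_sets",
    "drug_target_overlap",
    "act_surface_filter",
    "scrna_percent_expressed_filter",
    "nact_overlap",
    "multiomic_intersect",
]

FUNCTIONAL_CLASSES = (
    "kinase",
    "epigenetic_factor",
    "transcription_factor",
    "metabolism",
    "cell_surface",
)


def cpm_normalize(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: scale every sample (column) to sum to 1e6."""
    colsum = counts.sum(axis=0)
    if (colsum <= 0).any():
        bad = colsum[colsum <= 0].index.tolist()
        raise ValueError(f"zero-sum sample(s): {bad}")
    return counts * 1.0e6 / colsum


def differential_expression(
    counts: pd.DataFrame,
    groups: dict | pd.Series,
    paired: bool = False,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-gene tumor-vs-normal differential test on CPM.

    log2fc = log2((mean tumor CPM + 1) / (mean normal CPM + 1)); p-values from
    the two-sided Wilcoxon rank-sum test (signed-rank over per-pair
    differences when ``paired``) on log2(CPM + 1); BH adjustment across all
    genes. Returns a table with gene, log2fc, p_value, adj_p, mean_cpm_tumor,
    mean_cpm_normal.
    """
    groups = pd.Series(groups)
    tumor = [s for s in counts.columns if groups.get(s) == "tumor"]
    normal = [s for s in counts.columns if groups.get(s) == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError("need >= 2 samples per group")

    cpm = cpm_normalize(counts)
    mean_t = cpm[tumor].mean(axis=1)
    mean_n = cpm[normal].mean(axis=1)
    log2fc = np.log2((mean_t + 1.0) / (mean_n + 1.0))

    log_t = np.log2(cpm[tumor].to_numpy() + 1.0)
    log_n = np.log2(cpm[normal].to_numpy() + 1.0)

    if paired:
        if pairs is None:
            if len(tumor) != len(normal):
                raise ValueError("paired mode requires explicit pairing")
            pairs = list(zip(tumor, normal))
        t_cols = [counts.columns.get_loc(a) for a, _ in pairs]
        n_cols = [counts.columns.get_loc(b) for _, b in pairs]
        for a, b in pairs:
            if groups.get(a) != "tumor" or groups.get(b) != "normal":
                raise ValueError(f"unmatched pair ({a}, {b})")
        log_all = np.log2(cpm.to_numpy() + 1.0)
        diffs = log_all[:, t_cols] - log_all[:, n_cols]
        pvals = np.ones(len(counts))
        nonzero = np.any(diffs != 0, axis=1)
        if nonzero.any():
            res = stats.wilcoxon(
                diffs[nonzero], axis=1, zero_method="wilcox", method="auto"
            )
            pvals[nonzero] = res.pvalue
    else:
        res = stats.mannwhitneyu(log_t, log_n, axis=1, alternative="two-sided")
        pvals = np.asarray(res.pvalue)

    pvals = np.clip(pvals, 0.0, 1.0)
    adj = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene": counts.index,
            "log2fc": log2fc.to_numpy(),
            "p_value": pvals,
            "adj_p": adj,
            "mean_cpm_tumor": mean_t.to_numpy(),
            "mean_cpm_normal": mean_n.to_numpy(),
        }
    ).set_index("gene", drop=False)


def filter_tsg(
    records: pd.DataFrame, fc_min: float = 2.0, alpha: float = 0.05
) -> tuple[set, set]:
    """Up- and down-regulated significant gene sets.

    Fold-change bound inclusive (|log2fc| >= log2(fc_min)), alpha strict
    (adj_p < alpha). The up set is the tumor-specific gene (TSG) set.
    """
    lfc_min = np.log2(fc_min)
    sig = records["adj_p"] < alpha
    up = set(records.loc[sig & (records["log2fc"] >= lfc_min), "gene"])
    down = set(records.loc[sig & (records["log2fc"] <= -lfc_min), "gene"])
    return up, down


@dataclass
class PanCancerResult:
    specific: set     # genes with positive evidence of no up-regulation elsewhere
    unevaluated: set  # genes absent from the pan-cancer table (retained, flagged)

    @property
    def retained(self) -> set:
        return self.specific | self.unevaluated


def pan_cancer_exclude(tsgs: set, pan_table: pd.DataFrame) -> PanCancerResult:
    """Drop TSGs up-regulated in any other cancer type.

    ``pan_table`` has columns gene, cancer, up (boolean). Genes missing from
    the table are retained but reported separately as unevaluated, since
    exclusion requires positive evidence of up-regulation elsewhere.
    """
    flagged = set(pan_table.loc[pan_table["up"].astype(bool), "gene"])
    covered = set(pan_table["gene"])
    specific = {g for g in tsgs if g in covered and g not in flagged}
    unevaluated = {g for g in tsgs if g not in covered}
    return PanCancerResult(specific=specific, unevaluated=unevaluated)


def classify_functional_sets(tsgs: set, annotation: pd.DataFrame) -> dict:
    """Intersect the TSG set with each functional class.

    ``annotation`` has columns gene, class; a gene may carry several classes.
    Returns {class: set of TSGs in that class} over the closed vocabulary.
    """
    unknown = set(annotation["class"]) - set(FUNCTIONAL_CLASSES)
    if unknown:
        raise ValueError(f"unknown functional classes: {sorted(unknown)}")
    out = {c: set() for c in FUNCTIONAL_CLASSES}
    for gene, cls in zip(annotation["gene"], annotation["class"]):
        if gene in tsgs:
            out[cls].add(gene)
    return out


def drug_target_overlap(class_sets: dict, drug_targets: dict) -> dict:
    """Split each class into drug-targeted and untargeted genes.

    ``drug_targets`` maps drug -> iterable of target genes. Returns
    {class: {"targeted": set, "untargeted": set}} plus a "gene_drugs" inverse
    map gene -> sorted list of drugs hitting it.
    """
    targeted_union = set()
    gene_drugs: dict[str, set] = {}
    for drug, genes in drug_targets.items():
        for g in genes:
            targeted_union.add(g)
            gene_drugs.setdefault(g, set()).add(drug)
    out = {}
    for cls, genes in class_sets.items():
        out[cls] = {
            "targeted": genes & targeted_union,
            "untargeted": genes - targeted_union,
        }
    out["gene_drugs"] = {g: sorted(d) for g, d in gene_drugs.items()}
    return out


def act_surface_filter(
    tsgs: set,
    records: pd.DataFrame,
    surface_genes: set | None = None,
    fc_min: float = 4.0,
    cpm_min: float = 90.0,
) -> tuple[set, int]:
    """Adoptive-cell-therapy surface-target candidates.

    Candidates are cell-surface-annotated TSGs with |log2fc| >= log2(fc_min)
    and mean tumor CPM >= cpm_min (both inclusive). Genes lacking a CPM value
    are skipped; their count is returned alongside the passing set.
    """
    candidates = tsgs if surface_genes is None else (tsgs & set(surface_genes))
    lfc_min = np.log2(fc_min)
    passing = set()
    skipped = 0
    rec = records.set_index("gene") if records.index.name != "gene" else records
    for g in candidates:
        if g not in rec.index:
            skipped += 1
            continue
        row = rec.loc[g]
        cpm = row["mean_cpm_tumor"]
        if pd.isna(cpm):
            skipped += 1
            continue
        if abs(row["log2fc"]) >= lfc_min and cpm >= cpm_min:
            passing.add(g)
    return passing, skipped


def scrna_percent_expressed_filter(
    cell_matrix: pd.DataFrame,
    clusters: dict | pd.Series,
    pct_min: float = 0.25,
    broad_min_types: int = 5,
) -> pd.DataFrame:
    """Percent-expressed filter on a cells x genes single-cell count matrix.

    A gene qualifies in a cell type when the fraction of that type's cells
    with nonzero counts strictly exceeds ``pct_min``; it passes the filter
    when it qualifies in >= 1 type and is labelled broad when it qualifies in
    >= ``broad_min_types`` types. Returns a per-gene table with the qualifying
    types, pass and broad flags.
    """
    clusters = pd.Series(clusters)
    missing = set(cell_matrix.index) - set(clusters.index)
    if missing:
        raise ValueError(f"unclustered cells: {sorted(missing)[:5]} ...")
    rows = []
    pct_by_type = {}
    for ctype, cells in clusters.groupby(clusters).groups.items():
        cells = [c for c in cells if c in cell_matrix.index]
        if not cells:
            raise ValueError(f"empty cluster {ctype!r}")
        pct_by_type[ctype] = (cell_matrix.loc[cells] > 0).mean(axis=0)
    pct = pd.DataFrame(pct_by_type)
    for gene in cell_matrix.columns:
        qualifying = sorted(pct.columns[pct.loc[gene] > pct_min])
        rows.append(
            (gene, qualifying, len(qualifying) >= 1,
             len(qualifying) >= broad_min_types)
        )
    return pd.DataFrame(
        rows, columns=["gene", "cell_types", "passes", "broad"]
    ).set_index("gene", drop=False)


def nact_overlap(
    pre_post_records: pd.DataFrame,
    tsgs: set,
    fc_min: float = 2.0,
    alpha: float = 0.05,
) -> tuple[set, set]:
    """TSGs up- or down-regulated after neoadjuvant chemotherapy.

    ``pre_post_records`` is a paired post-vs-pre differential table; the
    significant up/down sets are intersected with the TSG set.
    """
    up, down = filter_tsg(pre_post_records, fc_min=fc_min, alpha=alpha)
    return up & tsgs, down & tsgs


def multiomic_intersect(
    rna_up: set, rna_down: set, protein_up: set, protein_down: set
) -> tuple[set, set]:
    """Genes changed in the same direction at both mRNA and protein level."""
    return rna_up & protein_up, rna_down & protein_down
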