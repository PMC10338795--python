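"""Alternative-splicing event classification and PSI-based screens.

Events are called by comparing the exon chains of two transcripts of the same
gene and typed as ES (exon skipping), A3SS / A5SS (alternative 3'/5' splice
sites, assigned relative to strand), IR (intron retention) or MEE (mutually
exclusive exons); differences not matching one of the five patterns are
reported as "complex" and excluded from the five-type counts.

Percent spliced in (PSI) is estimated from junction read counts with per-form
junction normalization,

    psi = (inc/n_inc_junctions) / (inc/n_inc_junctions + exc/n_exc_junctions),

reported missing below a total-coverage floor.  The differential screen tests
per-patient paired PSI differences (two-sided paired t-test, BH adjustment)
and calls events at |dPSI| > 0.10 (strict) and adjusted p < 0.01 (strict);
the heterogeneity screen flags events whose tumor PSI standard deviation
(n-1 denominator) strictly exceeds 0.15.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TranscriptModel",
    "ASEvent",
    "read_gtf_transcripts",
    "classify_as_events",
    "classify_gene_events",
    "compute_psi",
    "psi_matrix",
    "differential_as",
    "heterogeneity_screen",
    "specific_and_heterogeneous",
]

AS_TYPES = ("ES", "A3SS", "A5SS", "IR", "MEE")


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered chain of exons (0-based half-open)."""

    gene: str
    transcript: str
    chrom: str
    strand: str
    exons: tuple

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        if not exons:
            raise ValueError("transcript needs >= 1 exon")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError("exons must be non-overlapping and sorted")
        if any(s >= e for s, e in exons):
            raise ValueError("exon start must precede end")
        object.__setattr__(self, "exons", exons)


@dataclass(frozen=True)
class ASEvent:
    """One alternative-splicing event between two transcript forms."""

    event_id: str
    gene: str
    type: str
    chrom: str
    strand: str
    inclusion_form: tuple   # exon intervals specific to the inclusion form
    exclusion_form: tuple
    anchors: tuple          # (left anchor exon or None, right anchor exon or None)
    n_inc_junctions: int = 1
    n_exc_junctions: int = 1


def read_gtf_transcripts(path_or_text: str) -> list[TranscriptModel]:
    """Read exon features from a GTF file (or raw GTF text).

    Coordinates are converted from GTF's 1-based inclusive convention to
    0-based half-open storage.
    """
    import os

    if os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
    else:
        text = path_or_text

    chains: dict[tuple, list] = {}
    meta: dict[tuple, tuple] = {}
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 9 or f[2] != "exon":
            continue
        chrom, start, end, strand, attrs = f[0], int(f[3]), int(f[4]), f[6], f[8]
        gene = transcript = None
        for item in attrs.split(";"):
            item = item.strip()
            if item.startswith("gene_id"):
                gene = item.split('"')[1]
            elif item.startswith("transcript_id"):
                transcript = item.split('"')[1]
        if gene is None or transcript is None:
            raise ValueError(f"GTF exon lacks gene_id/transcript_id: {line!r}")
        key = (gene, transcript)
        chains.setdefault(key, []).append((start - 1, end))
        meta[key] = (chrom, strand)
    return [
        TranscriptModel(
            gene=g, transcript=t, chrom=meta[(g, t)][0],
            strand=meta[(g, t)][1], exons=tuple(exons),
        )
        for (g, t), exons in chains.items()
    ]


# ---------------------------------------------------------------------------
# event classification
# ---------------------------------------------------------------------------

def _bubbles(e1: tuple, e2: tuple):
    """Align exact-equal exons of two chains; yield the difference regions.

    Yields (left_anchor, u1, u2, right_anchor) where the anchors are matched
    exons (or None at transcript ends) and u1/u2 the unmatched exons of each
    transcript between them.
    """
    matches = []
    i = j = 0
    while i < len(e1) and j < len(e2):
        if e1[i] == e2[j]:
            matches.append((i, j))
            i += 1
            j += 1
        elif e1[i][0] < e2[j][0] or (e1[i][0] == e2[j][0] and e1[i][1] < e2[j][1]):
            i += 1
        else:
            j += 1
    bounds = [(-1, -1)] + matches + [(len(e1), len(e2))]
    for (i0, j0), (i1, j1) in zip(bounds, bounds[1:]):
        u1 = e1[i0 + 1:i1]
        u2 = e2[j0 + 1:j1]
        if not u1 and not u2:
            continue
        left = e1[i0] if i0 >= 0 else None
        right = e1[i1] if i1 < len(e1) else None
        yield left, u1, u2, right


def _consecutive(chain: tuple, a: tuple, b: tuple) -> bool:
    ia, ib = chain.index(a), chain.index(b)
    return ib == ia + 1


def _classify_bubble(left, u1, u2, right, strand, t1_exons, t2_exons):
    """Return (type, inclusion_form, exclusion_form, n_inc_j, n_exc_j) or complex."""
    # exon skipping: one side empty, exons strictly between shared flanks
    if (not u1 or not u2) and left is not None and right is not None:
        inc = u1 or u2
        k = len(inc)
        return "ES", tuple(inc), (), k + 1, 1

    # intron retention: one exon exactly spanning the other side's exon pair
    for ua, ub in ((u1, u2), (u2, u1)):
        if len(ua) == 1 and len(ub) == 2:
            span, pair = ua[0], ub
            chain = t1_exons if ua is u1 else t2_exons
            other = t2_exons if ua is u1 else t1_exons
            if (span[0] == pair[0][0] and span[1] == pair[1][1]
                    and _consecutive(other, pair[0], pair[1])):
                return "IR", (span,), tuple(pair), 1, 1

    if len(u1) == 1 and len(u2) == 1:
        x, y = u1[0], u2[0]
        overlap = x[0] < y[1] and y[0] < x[1]
        if not overlap and left is not None and right is not None:
            first, second = (x, y) if x[0] < y[0] else (y, x)
            return "MEE", (first,), (second,), 2, 2
        if overlap:
            if x[1] == y[1] and x[0] != y[0] and left is not None:
                # start (genomic-left) boundary shifts across a shared intron donor
                etype = "A3SS" if strand == "+" else "A5SS"
            elif x[0] == y[0] and x[1] != y[1] and right is not None:
                etype = "A5SS" if strand == "+" else "A3SS"
            else:
                return None
            longer, shorter = (x, y) if (x[1] - x[0]) > (y[1] - y[0]) else (y, x)
            return etype, (longer,), (shorter,), 1, 1
    return None


def classify_as_events(t1: TranscriptModel, t2: TranscriptModel) -> list[ASEvent]:
    """Call AS events between two transcripts of the same gene.

    Events are reported in genomic order with deterministic IDs
    ``<gene>.<type>.<k>``. Bubbles not matching any of the five patterns are
    emitted with type "complex".
    """
    if t1.gene != t2.gene:
        raise ValueError("transcripts belong to different genes")
    if t1.chrom != t2.chrom or t1.strand != t2.strand:
        raise ValueError("chrom/strand mismatch between transcripts")

    raw = []
    for left, u1, u2, right in _bubbles(t1.exons, t2.exons):
        res = _classify_bubble(left, u1, u2, right, t1.strand, t1.exons, t2.exons)
        pos = min(x[0] for x in (u1 + u2))
        if res is None:
            raw.append((pos, "complex", tuple(u1), tuple(u2), 1, 1, (left, right)))
        else:
            etype, inc, exc, nij, nej = res
            raw.append((pos, etype, inc, exc, nij, nej, (left, right)))

    raw.sort(key=lambda r: r[0])
    events = []
    counter: dict[str, int] = {}
    for pos, etype, inc, exc, nij, nej, anchors in raw:
        k = counter.get(etype, 0) + 1
        counter[etype] = k
        events.append(
            ASEvent(
                event_id=f"{t1.gene}.{etype}.{k}", gene=t1.gene, type=etype,
                chrom=t1.chrom, strand=t1.strand,
                inclusion_form=inc, exclusion_form=exc, anchors=anchors,
                n_inc_junctions=nij, n_exc_junctions=nej,
            )
        )
    return events


def classify_gene_events(transcripts: list[TranscriptModel]) -> list[ASEvent]:
    """All pairwise AS events within each gene of a transcript catalog."""
    from itertools import combinations

    by_gene: dict[str, list] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene, []).append(t)
    events = []
    for gene in sorted(by_gene):
        for t1, t2 in combinations(sorted(by_gene[gene], key=lambda t: t.transcript), 2):
            events.extend(classify_as_events(t1, t2))
    return events


# ---------------------------------------------------------------------------
# PSI
# ---------------------------------------------------------------------------

def compute_psi(
    inc_count: float,
    exc_count: float,
    inc_junctions: int = 1,
    exc_junctions: int = 1,
    min_total: int = 10,
) -> float:
    """Junction-normalized PSI; NaN below the coverage floor."""
    if inc_junctions < 1 or exc_junctions < 1:
        raise ValueError("junction counts per form must be >= 1")
    if inc_count < 0 or exc_count < 0:
        raise ValueError("read counts must be >= 0")
    if inc_count + exc_count < min_total:
        return float("nan")
    ri = inc_count / inc_junctions
    re = exc_count / exc_junctions
    if ri + re == 0:
        return float("nan")
    return ri / (ri + re)


def psi_matrix(
    junctions: pd.DataFrame,
    events: pd.DataFrame | None = None,
    min_total: int = 10,
) -> pd.DataFrame:
    """PSI per event (rows) per sample (columns) from a junction count table.

    ``junctions`` has columns event_id, sample_id, inc_count, exc_count;
    ``events``, when given, supplies per-event n_inc_junctions /
    n_exc_junctions for the normalization (1/1 otherwise).
    """
    nj = {}
    if events is not None:
        for r in events.itertuples():
            nj[r.event_id] = (int(r.n_inc_junctions), int(r.n_exc_junctions))
    psis = [
        compute_psi(
            r.inc_count, r.exc_count,
            *nj.get(r.event_id, (1, 1)), min_total=min_total,
        )
        for r in junctions.itertuples()
    ]
    long = junctions.assign(psi=psis)
    return long.pivot(index="event_id", columns="sample_id", values="psi")


def differential_as(
    psi: pd.DataFrame,
    pairing: list[tuple[str, str]],
    dpsi_min: float = 0.10,
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired tumor-vs-normal differential splicing screen.

    ``pairing`` lists (tumor_sample, normal_sample) pairs. Per event, pairs
    with a missing PSI on either side are dropped; events with < 3 complete
    pairs are excluded with a reason. dPSI is the mean of per-pair
    (tumor - normal) differences; p from a two-sided paired t-test with BH
    adjustment across tested events. Significant iff |dPSI| > dpsi_min and
    adj_p < alpha (both strict). Returns (results sorted by |dPSI| descending,
    excluded-events table).
    """
    tested, excluded = [], []
    for event_id, row in psi.iterrows():
        diffs = []
        for t, n in pairing:
            pt, pn = row.get(t, np.nan), row.get(n, np.nan)
            if np.isfinite(pt) and np.isfinite(pn):
                diffs.append(pt - pn)
        if len(diffs) < 3:
            excluded.append((event_id, f"only {len(diffs)} complete pairs"))
            continue
        diffs = np.asarray(diffs)
        dpsi = float(diffs.mean())
        if np.allclose(diffs.std(ddof=1), 0.0):
            p = 1.0 if np.isclose(dpsi, 0.0) else 0.0
        else:
            p = float(stats.ttest_rel(diffs, np.zeros_like(diffs)).pvalue)
        tested.append((event_id, dpsi, len(diffs), p))

    res = pd.DataFrame(tested, columns=["event_id", "dpsi", "n_pairs", "p_value"])
    if len(res):
        res["adj_p"] = multipletests(res["p_value"], method="fdr_bh")[1]
        res["significant"] = (res["dpsi"].abs() > dpsi_min) & (res["adj_p"] < alpha)
        res = res.reindex(
            res["dpsi"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    else:
        res["adj_p"] = []
        res["significant"] = []
    excl = pd.DataFrame(excluded, columns=["event_id", "reason"])
    return res, excl


def heterogeneity_screen(
    psi_tumor: pd.DataFrame, sd_min: float = 0.15
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flag events whose tumor PSI standard deviation strictly exceeds sd_min.

    Uses the sample SD (n-1 denominator) over non-missing tumor PSI values;
    events with < 3 values are excluded with a reason. Returns (results,
    excluded-events table).
    """
    rows, excluded = [], []
    for event_id, row in psi_tumor.iterrows():
        vals = row.to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size < 3:
            excluded.append((event_id, f"only {vals.size} tumor PSI values"))
            continue
        sd = float(np.std(vals, ddof=1))
        rows.append((event_id, sd, vals.size, sd > sd_min))
    res = pd.DataFrame(rows, columns=["event_id", "psi_sd", "n_samples", "heterogeneous"])
    excl = pd.DataFrame(excluded, columns=["event_id", "reason"])
    return res, excl


def specific_and_heterogeneous(
    differential: pd.DataFrame, heterogeneity: pd.DataFrame
) -> set:
    """Events that are both differentially spliced and patient-heterogeneous."""
    sig = set(differential.loc[differential["significant"], "event_id"])
    het = set(heterogeneity.loc[heterogeneity["heterogeneous"], "event_id"])
    return sig & het
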