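"""Synthetic data generators for every pipeline input.

Each generator is a pure function of its parameters and an integer seed, so
identical calls produce byte-identical outputs.  The generators emulate the
statistical structure the downstream analyses assume:

* 384-well viability plates with DMSO control wells and Hill-curve drug
  effects under multiplicative lognormal noise,
* pairwise drug-combination responses with optional planted Bliss-excess
  interactions,
* protein-protein interaction networks with a planted, densely connected
  hub module,
* negative-binomial tumor/normal count matrices with planted fold changes,
* binomial junction counts with planted PSI shifts and per-patient PSI
  heterogeneity, plus matching two-transcript gene models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScreenTruth",
    "InteractionTruth",
    "SplicingTruth",
    "PlateSet",
    "CombinationScreen",
    "hill_viability",
    "gen_screen_plates",
    "gen_dose_response_series",
    "gen_combination_screen",
    "gen_ppi_network",
    "gen_expression_counts",
    "gen_splicing_dataset",
]


# ---------------------------------------------------------------------------
# latent-truth records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenTruth:
    """Latent 4PL dose-response parameters for one drug.

    ic50 is in uM; ``top`` is fractional viability at zero dose (~1) and
    ``bottom`` the viability plateau at saturating dose.
    """

    drug_id: str
    ic50: float
    hill: float = 1.0
    top: float = 1.0
    bottom: float = 0.0

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError(f"ic50 must be > 0, got {self.ic50}")
        if self.hill <= 0:
            raise ValueError(f"hill must be > 0, got {self.hill}")
        if not self.top > self.bottom:
            raise ValueError("top must exceed bottom")
        if not 0 <= self.bottom < 1:
            raise ValueError("bottom must lie in [0, 1)")

    def viability(self, dose: float | np.ndarray) -> float | np.ndarray:
        return hill_viability(dose, self.top, self.bottom, self.ic50, self.hill)


@dataclass(frozen=True)
class InteractionTruth:
    """Planted deviation from Bliss independence for one drug pair.

    ``bliss_excess`` is added to the independent-action combined inhibition;
    0 means the drugs act independently.
    """

    drug_a: str
    drug_b: str
    bliss_excess: float = 0.0


@dataclass(frozen=True)
class SplicingTruth:
    """Latent inclusion levels for one alternative-splicing event."""

    event_id: str
    psi_normal: float
    psi_tumor: float
    tumor_psi_sd: float = 0.0
    event_type: str = "ES"

    def __post_init__(self) -> None:
        for name in ("psi_normal", "psi_tumor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.tumor_psi_sd <= 0.5:
            raise ValueError("tumor_psi_sd must lie in [0, 0.5]")
        if self.event_type not in {"ES", "A3SS", "A5SS", "IR", "MEE"}:
            raise ValueError(f"unknown event type {self.event_type!r}")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class PlateSet:
    """A set of wells with a plate map (drug wells plus DMSO controls)."""

    wells: pd.DataFrame  # columns: well, row, col, role, drug_id, dose_uM, signal

    def control_signals(self) -> np.ndarray:
        return self.wells.loc[self.wells["role"] == "control", "signal"].to_numpy()

    def drug_wells(self) -> pd.DataFrame:
        return self.wells[self.wells["role"] == "drug"]


@dataclass
class CombinationScreen:
    """Pairwise combination responses plus the single-agent anchors."""

    pairs: pd.DataFrame    # drug_a, drug_b, dose_a_uM, dose_b_uM, Po
    singles: pd.DataFrame  # drug, dose_uM, P


def hill_viability(dose, top, bottom, ic50, hill):
    """Four-parameter logistic viability: bottom + (top-bottom)/(1+(d/ic50)^hill)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ic50) ** hill)


def _lognormal_factor(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    sigma = np.sqrt(sigma2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=sigma, size=size)


# ---------------------------------------------------------------------------
# screen plates
# ---------------------------------------------------------------------------

_PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 384-well: 16 rows x 24 columns
_PLATE_COLS = 24

_CONTROL_SIGNAL = 1.0e6  # nominal luminescence of an untreated well


def _well_name(index: int) -> tuple[str, str, int]:
    plate, pos = divmod(index, len(_PLATE_ROWS) * _PLATE_COLS)
    r, c = divmod(pos, _PLATE_COLS)
    row, col = _PLATE_ROWS[r], c + 1
    return f"P{plate + 1}:{row}{col:02d}", row, col


def gen_screen_plates(
    truths: list[ScreenTruth],
    dose: float,
    n_control_wells: int = 16,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> PlateSet:
    """Simulate a fixed-dose viability screen: one well per drug plus controls.

    Drug-well signal = control mean x 4PL viability at ``dose`` x lognormal
    noise; control wells get the same multiplicative noise around the control
    mean. Well positions fill 384-well plates row-major, controls last.
    """
    if not truths:
        raise ValueError("truth list must not be empty")
    if dose <= 0:
        raise ValueError(f"dose must be positive, got {dose}")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)

    n = len(truths)
    via = np.array([t.viability(dose) for t in truths])
    drug_noise = _lognormal_factor(rng, noise_cv, n)
    ctrl_noise = _lognormal_factor(rng, noise_cv, n_control_wells)

    rows = []
    for i, t in enumerate(truths):
        well, r, c = _well_name(i)
        rows.append((well, r, c, "drug", t.drug_id, dose,
                     _CONTROL_SIGNAL * via[i] * drug_noise[i]))
    for j in range(n_control_wells):
        well, r, c = _well_name(n + j)
        rows.append((well, r, c, "control", None, 0.0,
                     _CONTROL_SIGNAL * ctrl_noise[j]))
    df = pd.DataFrame(
        rows, columns=["well", "row", "col", "role", "drug_id", "dose_uM", "signal"]
    )
    return PlateSet(wells=df)


def gen_dose_response_series(
    truth: ScreenTruth,
    doses: list[float],
    replicates: int = 3,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a dose-response series: (dose, replicate, viability) rows."""
    doses = list(doses)
    if not doses:
        raise ValueError("dose list must not be empty")
    if any(d <= 0 for d in doses):
        raise ValueError("all doses must be positive")
    if len(set(doses)) != len(doses):
        raise ValueError("doses must be distinct")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    d = np.repeat(np.asarray(doses, dtype=float), replicates)
    rep = np.tile(np.arange(1, replicates + 1), len(doses))
    via = truth.viability(d) * _lognormal_factor(rng, noise_cv, d.size)
    return pd.DataFrame({"dose_uM": d, "replicate": rep, "viability": via})


# ---------------------------------------------------------------------------
# combination screen
# ---------------------------------------------------------------------------

def gen_combination_screen(
    truths: list[ScreenTruth],
    interactions: list[InteractionTruth] | None = None,
    doses: dict[str, float] | None = None,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> CombinationScreen:
    """Simulate all C(n,2) pairwise combinations of the given drugs.

    Single-agent inhibitions Pa, Pb come noise-free from the 4PL truths at
    each drug's combination dose; the observed combined inhibition is
    Po = clamp(Pa + Pb - Pa*Pb + bliss_excess, 0, 1) x lognormal noise.
    """
    by_id = {t.drug_id: t for t in truths}
    interactions = interactions or []
    for it in interactions:
        if it.drug_a not in by_id or it.drug_b not in by_id:
            raise ValueError(f"interaction references unknown drug: {it.drug_a}/{it.drug_b}")
    if doses is None:
        doses = {t.drug_id: t.ic50 for t in truths}
    missing = [t.drug_id for t in truths if t.drug_id not in doses]
    if missing:
        raise ValueError(f"missing dose for drugs: {missing}")

    excess = {}
    for it in interactions:
        excess[frozenset((it.drug_a, it.drug_b))] = it.bliss_excess

    rng = np.random.default_rng(seed)
    drug_ids = [t.drug_id for t in truths]
    p_single = {d: 1.0 - by_id[d].viability(doses[d]) for d in drug_ids}

    pair_list = list(itertools.combinations(drug_ids, 2))
    noise = _lognormal_factor(rng, noise_cv, len(pair_list))
    rows = []
    for k, (a, b) in enumerate(pair_list):
        pa, pb = p_single[a], p_single[b]
        eps = excess.get(frozenset((a, b)), 0.0)
        po = np.clip(pa + pb - pa * pb + eps, 0.0, 1.0) * noise[k]
        rows.append((a, b, doses[a], doses[b], po))
    pairs = pd.DataFrame(rows, columns=["drug_a", "drug_b", "dose_a_uM", "dose_b_uM", "Po"])
    singles = pd.DataFrame(
        {"drug": drug_ids,
         "dose_uM": [doses[d] for d in drug_ids],
         "P": [p_single[d] for d in drug_ids]}
    )
    return CombinationScreen(pairs=pairs, singles=singles)


# ---------------------------------------------------------------------------
# PPI network with planted hubs
# ---------------------------------------------------------------------------

def gen_ppi_network(
    n_nodes: int = 200,
    n_planted_hubs: int = 8,
    background_degree: float = 4.0,
    seed: int = 0,
):
    """Random PPI-like graph with a planted hub module.

    Background edges follow a G(n, p) rule with p chosen so the mean degree is
    ``background_degree``. Planted hubs form a clique and each additionally
    attaches to 5 x background_degree random non-hub nodes, so they dominate
    the degree distribution the way curated hub genes dominate PPI networks.

    Returns (networkx.Graph, list of planted hub labels).
    """
    import networkx as nx

    if n_nodes < 3:
        raise ValueError("n_nodes must be >= 3")
    if n_planted_hubs >= n_nodes:
        raise ValueError("n_planted_hubs must be < n_nodes")
    rng = np.random.default_rng(seed)

    labels = [f"G{i:04d}" for i in range(n_nodes)]
    hubs = labels[:n_planted_hubs]
    background = labels[n_planted_hubs:]

    g = nx.Graph()
    g.add_nodes_from(labels)

    # background: fixed random-attachment rule (Bernoulli edges, mean degree fixed)
    p = min(1.0, background_degree / max(n_nodes - 1, 1))
    bg_n = len(background)
    mask = rng.random((bg_n, bg_n)) < p
    iu = np.triu_indices(bg_n, k=1)
    for i, j in zip(*iu):
        if mask[i, j]:
            g.add_edge(background[i], background[j])

    # planted module: clique among hubs ...
    for a, b in itertools.combinations(hubs, 2):
        g.add_edge(a, b)
    # ... plus heavy attachment into the background
    n_attach = int(round(5 * background_degree))
    for h in hubs:
        targets = rng.choice(len(background), size=min(n_attach, bg_n), replace=False)
        for t in targets:
            g.add_edge(h, background[t])
    return g, hubs


# ---------------------------------------------------------------------------
# expression counts
# ---------------------------------------------------------------------------

def gen_expression_counts(
    n_genes: int = 2000,
    n_tumor: int = 13,
    n_normal: int = 13,
    de_fraction: float = 0.1,
    lfc_magnitude: float = 2.0,
    dispersion: float = 0.05,
    seed: int = 0,
):
    """Negative-binomial tumor/normal counts with planted fold changes.

    Exactly round(de_fraction * n_genes) genes are differentially expressed,
    alternating up/down with tumor mean shifted by 2**(+-lfc_magnitude).
    Per-sample library-size factors are drawn uniformly in [0.7, 1.4] (within
    2x of each other). Returns (counts DataFrame genes x samples,
    truth DataFrame with columns gene, is_de, direction).
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    if min(n_tumor, n_normal) < 2:
        raise ValueError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)

    genes = [f"GENE{i:05d}" for i in range(n_genes)]
    samples = [f"T{i + 1:02d}" for i in range(n_tumor)] + [
        f"N{i + 1:02d}" for i in range(n_normal)
    ]
    base_mean = rng.lognormal(mean=np.log(150.0), sigma=1.0, size=n_genes)

    n_de = int(round(de_fraction * n_genes))
    direction = np.zeros(n_genes, dtype=int)
    de_idx = np.arange(n_de)
    direction[de_idx] = np.where(de_idx % 2 == 0, 1, -1)

    mu_normal = base_mean
    mu_tumor = base_mean * np.power(2.0, lfc_magnitude * direction)

    size_factors = rng.uniform(0.7, 1.4, size=n_tumor + n_normal)
    mu = np.empty((n_genes, n_tumor + n_normal))
    mu[:, :n_tumor] = mu_tumor[:, None] * size_factors[:n_tumor]
    mu[:, n_tumor:] = mu_normal[:, None] * size_factors[n_tumor:]

    if dispersion > 0:
        # NB with var = mu + dispersion * mu^2
        r = 1.0 / dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu)

    counts_df = pd.DataFrame(counts, index=genes, columns=samples)
    truth = pd.DataFrame(
        {"gene": genes,
         "is_de": direction != 0,
         "direction": direction}
    )
    return counts_df, truth


# ---------------------------------------------------------------------------
# splicing dataset
# ---------------------------------------------------------------------------

_EXON = 100      # exon length used in generated gene models
_INTRON = 100    # intron length

def _event_exons(event_type: str, offset: int):
    """Exon chains (0-based half-open) for the inclusion/exclusion transcripts."""
    o = offset
    if event_type == "ES":
        inc = [(o, o + 100), (o + 200, o + 300), (o + 400, o + 500)]
        exc = [(o, o + 100), (o + 400, o + 500)]
        n_inc_j, n_exc_j = 2, 1
    elif event_type == "A3SS":
        # acceptor of the second exon shifts (plus strand)
        inc = [(o, o + 100), (o + 180, o + 300)]
        exc = [(o, o + 100), (o + 200, o + 300)]
        n_inc_j, n_exc_j = 1, 1
    elif event_type == "A5SS":
        # donor of the first exon shifts (plus strand)
        inc = [(o, o + 120), (o + 200, o + 300)]
        exc = [(o, o + 100), (o + 200, o + 300)]
        n_inc_j, n_exc_j = 1, 1
    elif event_type == "IR":
        inc = [(o, o + 300)]                       # retained intron
        exc = [(o, o + 100), (o + 200, o + 300)]
        n_inc_j, n_exc_j = 1, 1
    elif event_type == "MEE":
        inc = [(o, o + 100), (o + 200, o + 300), (o + 600, o + 700)]
        exc = [(o, o + 100), (o + 400, o + 500), (o + 600, o + 700)]
        n_inc_j, n_exc_j = 2, 2
    else:  # pragma: no cover - guarded by SplicingTruth
        raise ValueError(event_type)
    return inc, exc, n_inc_j, n_exc_j


def _gtf_lines(gene: str, transcript: str, chrom: str, strand: str, exons) -> list[str]:
    out = []
    attrs = f'gene_id "{gene}"; transcript_id "{transcript}";'
    for start0, end0 in exons:
        # GTF is 1-based inclusive
        out.append(
            f"{chrom}\tsarcoscreen\texon\t{start0 + 1}\t{end0}\t.\t{strand}\t.\t{attrs}"
        )
    return out


def gen_splicing_dataset(
    truths: list[SplicingTruth],
    n_pairs: int = 13,
    coverage_mean: float = 100.0,
    seed: int = 0,
):
    """Binomial junction counts plus matching two-transcript gene models.

    For each event and sample the total junction reads are Poisson with mean
    ``coverage_mean``; the inclusion count is binomial with a probability
    adjusted for the number of junctions supporting each form, so the
    junction-normalized PSI estimator is consistent for the latent PSI.
    Tumor-sample PSI is drawn Normal(psi_tumor, tumor_psi_sd) truncated to
    [0, 1]; normal samples use psi_normal exactly.

    Returns (junctions DataFrame, gtf_text, events DataFrame).
    """
    if n_pairs < 3:
        raise ValueError("n_pairs must be >= 3")
    if coverage_mean < 10:
        raise ValueError("coverage_mean must be >= 10")
    rng = np.random.default_rng(seed)

    tumor_samples = [f"T{i + 1:02d}" for i in range(n_pairs)]
    normal_samples = [f"N{i + 1:02d}" for i in range(n_pairs)]

    gtf_lines: list[str] = []
    jrows = []
    erows = []
    offset = 1000
    for t in truths:
        gene = f"{t.event_id}_gene"
        inc, exc, n_inc_j, n_exc_j = _event_exons(t.event_type, offset)
        offset += 2000
        gtf_lines += _gtf_lines(gene, f"{gene}.inc", "chr1", "+", inc)
        gtf_lines += _gtf_lines(gene, f"{gene}.exc", "chr1", "+", exc)
        erows.append((t.event_id, gene, t.event_type, n_inc_j, n_exc_j))

        # per-sample latent PSI
        psi_t = np.clip(
            rng.normal(t.psi_tumor, t.tumor_psi_sd, size=n_pairs), 0.0, 1.0
        ) if t.tumor_psi_sd > 0 else np.full(n_pairs, t.psi_tumor)
        psi_n = np.full(n_pairs, t.psi_normal)

        for samples, psis in ((tumor_samples, psi_t), (normal_samples, psi_n)):
            totals = rng.poisson(coverage_mean, size=n_pairs)
            # junction-count model: reads land on inclusion junctions with
            # probability proportional to psi * n_inc_j
            w_inc = psis * n_inc_j
            w_exc = (1.0 - psis) * n_exc_j
            with np.errstate(invalid="ignore"):
                p_inc = np.where(w_inc + w_exc > 0, w_inc / (w_inc + w_exc), 0.0)
            inc_counts = rng.binomial(totals, p_inc)
            for s, tot, ic in zip(samples, totals, inc_counts):
                jrows.append((t.event_id, s, int(ic), int(tot - ic)))

    junctions = pd.DataFrame(
        jrows, columns=["event_id", "sample_id", "inc_count", "exc_count"]
    )
    events = pd.DataFrame(
        erows, columns=["event_id", "gene", "type", "n_inc_junctions", "n_exc_junctions"]
    )
    gtf_text = "\n".join(gtf_lines) + "\n"
    return junctions, gtf_text, events
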