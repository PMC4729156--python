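"""Synthetic annotations, expression models, and fragment simulation.

The generator emulates a two-condition RNA-seq experiment (three
biological replicates per condition by default) on a synthetic
single-chromosome genome, in one of two transcriptome regimes:

* ``fruitfly_like`` -- long exons, few isoforms per gene (2-3 typical);
* ``human_like``    -- short exons, many isoforms per gene.

Expression follows a hierarchical model.  Each gene g receives a
baseline expected count mu_g (log-normal, scaled so the expected counts
sum to the library size net of background) and a negative-binomial
dispersion phi_g from the mean-dispersion relationship
phi = a0 + a1/mu.  Isoform proportions pi_g are drawn once from a
sparse symmetric Dirichlet (producing dominant and near-zero isoforms)
and shared by both conditions.  Differential transcript usage is
introduced for selected genes by swapping the proportions of the two
most abundant isoforms in condition 2; gene-level expression is left
untouched, so DTU carries no gene-level differential expression.

Per sample, the realized gene count is NB(mu_g, phi_g); realized
isoform fractions are Dirichlet with concentration ``dirichlet_scale *
pi_g``; isoform RPK (reads per kilobase of effective length) and TPM
follow, and paired-end fragments are drawn from the isoforms with
probability proportional to TPM x effective length, plus a uniform
non-specific background component.  Fragments are emitted as exact
coordinate blocks (the genomic projection of the first and last
``read_length`` bases of each fragment), so counting operates on true
alignments with no read-level error model.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation import Annotation, Gene, GenomicInterval, Transcript

logger = logging.getLogger(__name__)

CHROM = "simchr"

#: Regime presets: exon/intron geometry and isoform-count weights.
REGIMES = {
    "fruitfly_like": {
        "isoform_count_weights": {1: 0.10, 2: 0.50, 3: 0.40},
        "exon_count_weights": {3: 0.2, 4: 0.3, 5: 0.3, 6: 0.2},
        "exon_length_meanlog": np.log(350.0),
        "exon_length_sdlog": 0.45,
        "intron_length_meanlog": np.log(800.0),
        "intron_length_sdlog": 0.5,
    },
    "human_like": {
        "isoform_count_weights": {3: 0.15, 4: 0.25, 5: 0.25, 6: 0.15, 8: 0.12, 10: 0.08},
        "exon_count_weights": {5: 0.2, 6: 0.2, 7: 0.2, 8: 0.2, 10: 0.2},
        "exon_length_meanlog": np.log(140.0),
        "exon_length_sdlog": 0.45,
        "intron_length_meanlog": np.log(1500.0),
        "intron_length_sdlog": 0.6,
    },
}


@dataclass
class SimParams:
    """Full parameterization of one simulated experiment.

    ``library_size`` is the desk-scale number of fragments per sample
    (2e5 by default) and also sets the scale of the expected gene
    counts.  ``n_dtu`` genes are switched; eligibility requires at least
    two isoforms with relative abundance above ``dtu_min_fraction`` and
    an expected gene count above ``dtu_min_count``.
    """

    n_genes: int = 300
    regime: str = "fruitfly_like"
    isoform_count_distribution: dict | None = None
    exon_length_distribution: tuple[float, float] | None = None  # (meanlog, sdlog)
    exon_count_distribution: dict | None = None
    intron_length_distribution: tuple[float, float] | None = None
    n_replicates_per_condition: int = 3
    library_size: int = 200_000
    background_fraction: float = 0.05
    fragment_length_mean: float = 250.0
    fragment_length_sd: float = 25.0
    read_length: int = 101
    dirichlet_scale: float = 100.0
    n_dtu: int = 60
    dtu_min_fraction: float = 0.10
    dtu_min_count: float = 500.0
    mu_sdlog: float = 0.7
    pi_concentration: float = 0.5
    dispersion_coeffs: tuple[float, float] = (0.01, 3.0)
    dispersion_jitter_sd: float = 0.0
    gene_overlap_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        for frac in (self.background_fraction, self.dtu_min_fraction,
                     self.gene_overlap_rate):
            if not (0 <= frac <= 1):
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_dtu > self.n_genes:
            raise ValueError("n_dtu cannot exceed n_genes")
        preset = REGIMES[self.regime]
        if self.isoform_count_distribution is None:
            self.isoform_count_distribution = dict(preset["isoform_count_weights"])
        if self.exon_count_distribution is None:
            self.exon_count_distribution = dict(preset["exon_count_weights"])
        if self.exon_length_distribution is None:
            self.exon_length_distribution = (
                preset["exon_length_meanlog"], preset["exon_length_sdlog"])
        if self.intron_length_distribution is None:
            self.intron_length_distribution = (
                preset["intron_length_meanlog"], preset["intron_length_sdlog"])

    def to_json(self) -> str:
        d = asdict(self)
        d["isoform_count_distribution"] = {
            str(k): v for k, v in self.isoform_count_distribution.items()
        }
        d["exon_count_distribution"] = {
            str(k): v for k, v in self.exon_count_distribution.items()
        }
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimParams":
        d = json.loads(text)
        for key in ("isoform_count_distribution", "exon_count_distribution"):
            if d.get(key) is not None:
                d[key] = {int(k): v for k, v in d[key].items()}
        for key in ("exon_length_distribution", "intron_length_distribution",
                    "dispersion_coeffs"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Annotation generation
# ---------------------------------------------------------------------------

def require_seed(params: "SimParams") -> int:
    """The simulation is a pure function of the seed; demand one."""
    if params.seed is None:
        raise ValueError("a simulation seed is required")
    return int(params.seed)


def _sample_weighted(rng, weights: dict[int, float]) -> int:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return int(rng.choice(keys, p=p / p.sum()))


MIN_EXON = 30
MIN_INTRON = 60


def _derive_isoform(rng, exons: list[tuple[int, int]]) -> list[tuple[int, int]] | None:
    """Apply one random structural edit to an exon chain.

    Edits: skip an internal exon, shift a 5'/3' exon boundary inward, or
    retain an intron (merge two consecutive exons).  Returns None if no
    edit is applicable.
    """
    n = len(exons)
    choices = []
    if n >= 3:
        choices.append("skip")
    if n >= 1:
        choices.append("alt_boundary")
    if n >= 2:
        choices.append("retained_intron")
    if not choices:
        return None
    edit = rng.choice(choices)
    exons = [list(e) for e in exons]
    if edit == "skip":
        i = int(rng.integers(1, n - 1))
        del exons[i]
    elif edit == "retained_intron":
        i = int(rng.integers(0, n - 1))
        exons[i][1] = exons[i + 1][1]
        del exons[i + 1]
    else:  # alt_boundary
        i = int(rng.integers(0, n))
        s, e = exons[i]
        room = (e - s) - MIN_EXON
        if room < 20:
            return None
        delta = int(rng.integers(20, room + 1))
        if rng.random() < 0.5:
            exons[i][0] = s + delta
        else:
            exons[i][1] = e - delta
    return [tuple(e) for e in exons]


def generate_annotation(params: SimParams) -> Annotation:
    """Generate a synthetic catalog on one chromosome.

    Genes are placed left to right without overlap by default; with
    ``gene_overlap_rate`` > 0 a fraction of genes is placed so its first
    exon overlaps the previous gene's last exon on the same strand,
    exercising the aggregation path of flattening.  Additional isoforms
    are derived from a primary transcript by repeated structural edits,
    and duplicated structures within a gene are rejected.
    """
    if params.n_genes <= 0:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([require_seed(params), 101]))
    exl_mean, exl_sd = params.exon_length_distribution
    inl_mean, inl_sd = params.intron_length_distribution
    genes = []
    cursor = 1000
    prev: Gene | None = None
    for gi in range(params.n_genes):
        gid = f"g{gi + 1:04d}"
        n_exons = _sample_weighted(rng, params.exon_count_distribution)
        exon_lens = np.maximum(
            MIN_EXON, rng.lognormal(exl_mean, exl_sd, size=n_exons).astype(int)
        )
        intron_lens = np.maximum(
            MIN_INTRON, rng.lognormal(inl_mean, inl_sd, size=max(n_exons - 1, 0)).astype(int)
        )
        overlap_prev = (
            prev is not None
            and params.gene_overlap_rate > 0
            and rng.random() < params.gene_overlap_rate
        )
        if overlap_prev:
            last = prev.exon_union()[-1]
            ov = int(min(20, last[1] - last[0], exon_lens[0]))
            start = last[1] - ov
            strand = prev.strand
        else:
            start = cursor + int(rng.integers(500, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
        exons = []
        pos = start
        for k in range(n_exons):
            exons.append((pos, pos + int(exon_lens[k])))
            pos = exons[-1][1]
            if k < n_exons - 1:
                pos += int(intron_lens[k])
        n_iso = _sample_weighted(rng, params.isoform_count_distribution)
        structures = [tuple(map(tuple, exons))]
        attempts = 0
        while len(structures) < n_iso and attempts < 50:
            attempts += 1
            base = structures[int(rng.integers(0, len(structures)))]
            alt = _derive_isoform(rng, [list(e) for e in base])
            if alt is not None and tuple(alt) not in structures:
                structures.append(tuple(alt))
        txs = [
            Transcript(
                f"{gid}.t{k + 1}",
                gid,
                [GenomicInterval(CHROM, s, e, strand) for s, e in struct],
            )
            for k, struct in enumerate(structures)
        ]
        gene = Gene(gid, txs)
        genes.append(gene)
        prev = gene
        cursor = max(cursor, exons[-1][1])
    return Annotation(genes, provenance=f"synthetic({params.regime},seed={params.seed})")


def chromosome_length(ann: Annotation) -> int:
    return max(t.span.end for g in ann.genes for t in g.transcripts) + 1000


# ---------------------------------------------------------------------------
# Expression model
# ---------------------------------------------------------------------------

def effective_length(L: int, fragment_mean: float) -> float:
    """Number of valid fragment start positions: max(1, L - mean + 1)."""
    if L < 1:
        raise ValueError("length must be >= 1")
    return max(1.0, L - fragment_mean + 1.0)


def dispersion_from_mean(
    mu: float, coeffs: tuple[float, float] = (0.01, 3.0),
    jitter_sd: float = 0.0, rng=None,
) -> float:
    """Mean-dispersion relationship phi = a0 + a1/mu, optional log-jitter."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    a0, a1 = coeffs
    phi = a0 + a1 / mu
    if jitter_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        phi = float(np.exp(np.log(phi) + rng.normal(0.0, jitter_sd)))
    return float(phi)


@dataclass
class ExpressionModel:
    """Per-gene NB means/dispersions and per-isoform proportions.

    ``pi1``/``pi2`` map gene_id -> proportion vector in conditions 1 and
    2 (parallel to ``isoforms[gene_id]``); both sum to one per gene.
    ``gene_eff_len`` is the expression-weighted mean of the isoform
    effective lengths under the baseline proportions.
    """

    gene_ids: list[str]
    mu: np.ndarray
    phi: np.ndarray
    gene_eff_len: np.ndarray
    isoforms: dict[str, list[str]]
    pi1: dict[str, np.ndarray]
    pi2: dict[str, np.ndarray]
    tx_len: dict[str, int]
    tx_eff_len: dict[str, float]

    def to_json(self) -> str:
        return json.dumps({
            "gene_ids": self.gene_ids,
            "mu": self.mu.tolist(),
            "phi": self.phi.tolist(),
            "gene_eff_len": self.gene_eff_len.tolist(),
            "isoforms": self.isoforms,
            "pi1": {g: v.tolist() for g, v in self.pi1.items()},
            "pi2": {g: v.tolist() for g, v in self.pi2.items()},
            "tx_len": self.tx_len,
            "tx_eff_len": self.tx_eff_len,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ExpressionModel":
        d = json.loads(text)
        return cls(
            gene_ids=d["gene_ids"],
            mu=np.asarray(d["mu"]),
            phi=np.asarray(d["phi"]),
            gene_eff_len=np.asarray(d["gene_eff_len"]),
            isoforms=d["isoforms"],
            pi1={g: np.asarray(v) for g, v in d["pi1"].items()},
            pi2={g: np.asarray(v) for g, v in d["pi2"].items()},
            tx_len=d["tx_len"],
            tx_eff_len=d["tx_eff_len"],
        )

    def copy(self) -> "ExpressionModel":
        return ExpressionModel(
            gene_ids=list(self.gene_ids),
            mu=self.mu.copy(),
            phi=self.phi.copy(),
            gene_eff_len=self.gene_eff_len.copy(),
            isoforms={g: list(v) for g, v in self.isoforms.items()},
            pi1={g: v.copy() for g, v in self.pi1.items()},
            pi2={g: v.copy() for g, v in self.pi2.items()},
            tx_len=dict(self.tx_len),
            tx_eff_len=dict(self.tx_eff_len),
        )


def build_expression_model(ann: Annotation, params: SimParams) -> ExpressionModel:
    """Draw baseline expression for every gene in the catalog.

    mu_g ~ log-normal scaled so sum(mu) = library_size * (1 - background);
    pi_g ~ symmetric Dirichlet(concentration < 1), sorted descending so
    isoform 1 is the dominant one; phi_g from the mean-dispersion curve.
    Condition-2 proportions start equal to condition-1 (no DTU yet).
    """
    rng = np.random.default_rng(np.random.SeedSequence([require_seed(params), 202]))
    gene_ids = [g.gene_id for g in ann.genes]
    n = len(gene_ids)
    raw = rng.lognormal(mean=0.0, sigma=params.mu_sdlog, size=n)
    mu = raw / raw.sum() * params.library_size * (1.0 - params.background_fraction)
    isoforms, pi1, pi2, tx_len, tx_eff = {}, {}, {}, {}, {}
    gene_eff = np.empty(n)
    for i, g in enumerate(ann.genes):
        tids = [t.transcript_id for t in g.transcripts]
        k = len(tids)
        if k == 1:
            pi = np.array([1.0])
        else:
            pi = rng.dirichlet(np.full(k, params.pi_concentration))
            pi = np.sort(pi)[::-1]
        isoforms[g.gene_id] = tids
        pi1[g.gene_id] = pi
        pi2[g.gene_id] = pi.copy()
        for t in g.transcripts:
            tx_len[t.transcript_id] = t.length
            tx_eff[t.transcript_id] = effective_length(
                t.length, params.fragment_length_mean
            )
        gene_eff[i] = float(
            np.dot(pi, [tx_eff[t] for t in tids])
        )
    phi = np.array([
        dispersion_from_mean(
            m, params.dispersion_coeffs, params.dispersion_jitter_sd, rng
        )
        for m in mu
    ])
    return ExpressionModel(
        gene_ids=gene_ids, mu=mu, phi=phi, gene_eff_len=gene_eff,
        isoforms=isoforms, pi1=pi1, pi2=pi2, tx_len=tx_len, tx_eff_len=tx_eff,
    )


# ---------------------------------------------------------------------------
# Ground truth and the DTU switch
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "gene_id", "dtu_status", "tx_swap_1", "tx_swap_2",
    "n_isoforms", "dominance_diff", "expected_count",
]


def select_dtu_genes(model: ExpressionModel, params: SimParams) -> pd.DataFrame:
    """Pick the genes to switch and build the full truth table.

    Eligibility: at least two isoforms with baseline relative abundance
    above ``dtu_min_fraction`` and expected gene count above
    ``dtu_min_count``.  ``dominance_diff`` is the difference in relative
    abundance between the two most abundant isoforms (the effect size of
    the swap); recorded for every gene.
    """
    rng = np.random.default_rng(np.random.SeedSequence([require_seed(params), 303]))
    rows = []
    eligible = []
    for i, gid in enumerate(model.gene_ids):
        pi = model.pi1[gid]
        n_expressed = int(np.sum(pi > params.dtu_min_fraction))
        ok = n_expressed >= 2 and model.mu[i] > params.dtu_min_count
        if ok:
            eligible.append(gid)
        top = np.sort(pi)[::-1]
        dom = float(top[0] - top[1]) if len(top) >= 2 else 1.0
        rows.append(
            dict(gene_id=gid, dtu_status=False, tx_swap_1="", tx_swap_2="",
                 n_isoforms=len(pi), dominance_diff=dom,
                 expected_count=float(model.mu[i]))
        )
    if len(eligible) < params.n_dtu:
        raise ValueError(
            f"only {len(eligible)} genes eligible for DTU, need {params.n_dtu}"
        )
    chosen = set(rng.choice(eligible, size=params.n_dtu, replace=False))
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    for idx, row in truth.iterrows():
        gid = row["gene_id"]
        if gid not in chosen:
            continue
        pi = model.pi1[gid]
        order = np.argsort(-pi, kind="stable")
        i1, i2 = order[0], order[1]
        truth.loc[idx, "dtu_status"] = True
        truth.loc[idx, "tx_swap_1"] = model.isoforms[gid][i1]
        truth.loc[idx, "tx_swap_2"] = model.isoforms[gid][i2]
    return truth


def apply_dtu_swap(model: ExpressionModel, truth: pd.DataFrame) -> ExpressionModel:
    """Swap the two most abundant isoform proportions in condition 2.

    Gene means are untouched, so there is no gene-level differential
    expression by construction.
    """
    out = model.copy()
    for _, row in truth[truth["dtu_status"].astype(bool)].iterrows():
        gid = row["gene_id"]
        pi = out.pi1[gid]
        if len(pi) < 2:
            raise ValueError(f"DTU gene {gid} has fewer than 2 isoforms")
        order = np.argsort(-pi, kind="stable")
        i1, i2 = order[0], order[1]
        pi2 = pi.copy()
        pi2[i1], pi2[i2] = pi[i2], pi[i1]
        out.pi2[gid] = pi2
    return out


# ---------------------------------------------------------------------------
# Per-sample expression
# ---------------------------------------------------------------------------

@dataclass
class SampleExpression:
    """Realized expression for one sample.

    ``gene_counts`` is parallel to the model's gene_ids; ``table`` holds
    one row per isoform with realized fraction, RPK, TPM, and the
    normalized fragment-sampling weight.
    """

    sample_id: str
    condition: int
    gene_counts: np.ndarray
    table: pd.DataFrame  # gene_id, transcript_id, frac, rpk, tpm, weight


def _nb_draw(rng, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB with mean mu and variance mu + phi mu^2 (Poisson when phi ~ 0)."""
    out = np.empty(len(mu), dtype=np.int64)
    tiny = phi < 1e-12
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    rest = ~tiny
    if rest.any():
        n = 1.0 / phi[rest]
        p = n / (n + mu[rest])
        out[rest] = rng.negative_binomial(n, p)
    return out


def simulate_sample_expression(
    model: ExpressionModel, condition: int, sample_id: str,
    params: SimParams, rng=None,
) -> SampleExpression:
    """Realize gene counts, isoform fractions, RPK/TPM for one sample.

    Isoforms with exactly-zero model proportion are excluded from the
    Dirichlet draw (its concentration is undefined at zero) and keep
    fraction zero.
    """
    if condition not in (1, 2):
        raise ValueError("condition must be 1 or 2")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([require_seed(params), 404, condition,
                                    zlib.crc32(sample_id.encode()) % (2**31)])
        )
    K = _nb_draw(rng, model.mu, model.phi)
    pi_cond = model.pi1 if condition == 1 else model.pi2
    rows = []
    gene_rpk = K / (model.gene_eff_len / 1000.0)
    for i, gid in enumerate(model.gene_ids):
        pi = pi_cond[gid]
        tids = model.isoforms[gid]
        frac = np.zeros(len(pi))
        nz = pi > 0
        if nz.sum() == 1:
            frac[nz] = 1.0
        elif nz.sum() > 1:
            frac[nz] = rng.dirichlet(params.dirichlet_scale * pi[nz])
        for j, tid in enumerate(tids):
            rows.append((gid, tid, frac[j], gene_rpk[i] * frac[j]))
    tab = pd.DataFrame(rows, columns=["gene_id", "transcript_id", "frac", "rpk"])
    total_rpk = tab["rpk"].sum()
    tab["tpm"] = 0.0 if total_rpk == 0 else 1e6 * tab["rpk"] / total_rpk
    eff = tab["transcript_id"].map(model.tx_eff_len)
    w = tab["tpm"].to_numpy() * eff.to_numpy()
    tab["weight"] = w / w.sum() if w.sum() > 0 else 0.0
    return SampleExpression(
        sample_id=sample_id, condition=condition, gene_counts=K, table=tab
    )


# ---------------------------------------------------------------------------
# Fragments
# ---------------------------------------------------------------------------

@dataclass
class Fragment:
    """A paired-end fragment as exact genomic alignment blocks."""

    fragment_id: str
    origin: str  # transcript_id or "background"
    mate1_blocks: list[GenomicInterval]
    mate2_blocks: list[GenomicInterval]
    sample_id: str


def project_to_genome(
    tx: Transcript, tx_start: int, tx_end: int
) -> list[GenomicInterval]:
    """Map a transcript-coordinate interval to genomic blocks.

    Transcript coordinates run along the genome (left to right over the
    exon chain); the library is unstranded so orientation is immaterial
    for counting.
    """
    if not (0 <= tx_start < tx_end <= tx.length):
        raise ValueError("interval outside transcript")
    blocks = []
    offset = 0
    for e in tx.exons:
        elen = len(e)
        lo = max(tx_start, offset)
        hi = min(tx_end, offset + elen)
        if lo < hi:
            blocks.append(
                GenomicInterval(e.chrom, e.start + lo - offset, e.start + hi - offset, e.strand)
            )
        offset += elen
    return blocks


def simulate_fragments(
    ann: Annotation, sample_expr: SampleExpression, params: SimParams,
    rng=None,
) -> list[Fragment]:
    """Draw the sample's fragments.

    round(background_fraction * N) fragments are uniform single-block
    pairs anywhere on the chromosome; the rest pick a transcript
    multinomially by the TPM x effective-length weight, a length from a
    truncated normal, and a uniform start.  Mates are the genomic
    projections of the first and last ``read_length`` fragment bases.
    Transcripts shorter than ``read_length`` are excluded from sampling.
    """
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([require_seed(params), 505, sample_expr.condition,
                                    zlib.crc32(sample_expr.sample_id.encode()) % (2**31)])
        )
    txs = ann.transcripts()
    N = params.library_size
    n_bg = int(round(params.background_fraction * N))
    n_tx = N - n_bg
    tab = sample_expr.table
    w = tab["weight"].to_numpy().copy()
    too_short = tab["transcript_id"].map(lambda t: txs[t].length < params.read_length)
    if too_short.any() and w[too_short.to_numpy()].sum() > 0:
        logger.warning(
            "%d transcripts shorter than read length excluded from sampling",
            int(too_short.sum()),
        )
        w[too_short.to_numpy()] = 0.0
    if w.sum() == 0:
        raise ValueError("no transcript has positive sampling weight")
    w = w / w.sum()
    choice = rng.choice(len(w), size=n_tx, p=w)
    rl = params.read_length
    fragments: list[Fragment] = []
    sid = sample_expr.sample_id
    tids = tab["transcript_id"].to_numpy()
    counts = np.bincount(choice, minlength=len(w))
    fi = 0
    for j in np.nonzero(counts)[0]:
        tx = txs[tids[j]]
        m = int(counts[j])
        flen = np.rint(
            rng.normal(params.fragment_length_mean, params.fragment_length_sd, size=m)
        ).astype(int)
        flen = np.clip(flen, rl, tx.length)
        starts = rng.integers(0, tx.length - flen + 1)
        for s, L in zip(starts, flen):
            m1 = project_to_genome(tx, int(s), int(s) + rl)
            m2 = project_to_genome(tx, int(s) + int(L) - rl, int(s) + int(L))
            fragments.append(
                Fragment(f"{sid}_f{fi:07d}", tx.transcript_id, m1, m2, sid)
            )
            fi += 1
    if n_bg == 0:
        return fragments
    chrom_len = chromosome_length(ann)
    flen = np.rint(
        rng.normal(params.fragment_length_mean, params.fragment_length_sd, size=n_bg)
    ).astype(int)
    flen = np.clip(flen, rl, None)
    starts = rng.integers(0, max(chrom_len - flen.max() - 1, 1), size=n_bg)
    for s, L in zip(starts, flen):
        s, L = int(s), int(L)
        fragments.append(
            Fragment(
                f"{sid}_f{fi:07d}", "background",
                [GenomicInterval(CHROM, s, s + rl, "+")],
                [GenomicInterval(CHROM, s + L - rl, s + L, "+")],
                sid,
            )
        )
        fi += 1
    return fragments


# ---------------------------------------------------------------------------
# Fragment and truth I/O
# ---------------------------------------------------------------------------

def write_fragments_bed12(fragments: list[Fragment], path) -> None:
    """One BED12 line per mate; blocks encode the splice structure."""
    with open(path, "w") as fh:
        for f in fragments:
            for mate, blocks in ((1, f.mate1_blocks), (2, f.mate2_blocks)):
                start = blocks[0].start
                end = blocks[-1].end
                sizes = ",".join(str(len(b)) for b in blocks)
                offs = ",".join(str(b.start - start) for b in blocks)
                fh.write(
                    "\t".join([
                        blocks[0].chrom, str(start), str(end),
                        f"{f.fragment_id}/{mate};{f.origin};{f.sample_id}",
                        "0", "+", str(start), str(end), "0",
                        str(len(blocks)), sizes, offs,
                    ]) + "\n"
                )


def read_fragments_bed12(path) -> list[Fragment]:
    frags: dict[str, Fragment] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            chrom, start = fields[0], int(fields[1])
            name, origin, sample_id = fields[3].split(";")
            fid, mate = name.rsplit("/", 1)
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            offs = [int(x) for x in fields[11].rstrip(",").split(",")]
            blocks = [
                GenomicInterval(chrom, start + o, start + o + s, fields[5])
                for o, s in zip(offs, sizes)
            ]
            if fid not in frags:
                frags[fid] = Fragment(fid, origin, [], [], sample_id)
            if mate == "1":
                frags[fid].mate1_blocks = blocks
            else:
                frags[fid].mate2_blocks = blocks
    return list(frags.values())


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    missing = [c for c in TRUTH_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"truth table missing columns: {missing}")
    tab["dtu_status"] = tab["dtu_status"].astype(bool)
    for col in ("tx_swap_1", "tx_swap_2"):
        tab[col] = tab[col].fillna("").astype(str)
    return tab


def true_abundance_table(model: ExpressionModel) -> pd.DataFrame:
    """Per-isoform true relative abundance in each condition (the input
    to true-abundance prefiltering)."""
    rows = []
    for gid in model.gene_ids:
        for j, tid in enumerate(model.isoforms[gid]):
            rows.append((tid, gid, model.pi1[gid][j], model.pi2[gid][j]))
    return pd.DataFrame(rows, columns=["isoform_id", "gene_id", "cond1", "cond2"])


def sample_abundance_table(samples: list[SampleExpression]) -> pd.DataFrame:
    """Per-isoform realized fraction per sample (the input to
    estimated-abundance prefiltering)."""
    base = samples[0].table[["transcript_id", "gene_id"]].rename(
        columns={"transcript_id": "isoform_id"}
    )
    for s in samples:
        base[s.sample_id] = s.table["frac"].to_numpy()
    return base
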