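"""Barcode-vs-metabarcode population diversity comparison.

Full-length COI population datasets are trimmed to the 313-nt Leray window
(amino acids 130-236 of the translated gene), haplotypes and SNP sites are
counted on both fragments, the posterior number of population clusters K is
estimated per fragment by a collapsed Bayesian mixture MCMC, and the paired
decrease in K under trimming is tested with a one-tailed Wilcoxon
signed-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np
from scipy import stats

from .seqs import DNA, parse_cigar


@dataclass(frozen=True)
class LerayWindow:
    """Leray window in reference-gene coordinates (1-based amino acids)."""

    aa_start: int = 130
    aa_end: int = 236
    expected_nt_length: int = 313

    @property
    def nt_start(self) -> int:
        return (self.aa_start - 1) * 3

    @property
    def nt_end(self) -> int:
        return self.nt_start + self.expected_nt_length


@dataclass
class WindowReport:
    seq_id: str
    covered: bool
    start_in_seq: int = -1
    end_in_seq: int = -1
    trimmed_length: int = 0


def locate_and_trim(
    seqs: list[tuple[str, str]],
    ref_gene: str,
    code_id: int,
    window: LerayWindow | None = None,
) -> tuple[list[tuple[str, str]], list[WindowReport]]:
    """Cut each dataset sequence to the Leray window of the reference gene.

    Each sequence is infix-aligned to the full-length gene; the window's
    reference coordinates are back-mapped through the alignment, so an
    in-frame deletion inside the window shortens the trimmed sequence
    accordingly. Sequences not fully covering the window are excluded and
    reported. Raises if nothing covers the window.
    """
    window = window or LerayWindow()
    w0, w1 = window.nt_start, window.nt_end
    trimmed: list[tuple[str, str]] = []
    reports: list[WindowReport] = []
    for sid, seq in seqs:
        seq = seq.upper()
        res = edlib.align(seq, ref_gene.upper(), mode="HW", task="path")
        g0 = res["locations"][0][0]
        gpos, spos = g0, 0
        s_start = s_end = None
        if gpos <= w0:
            for length, op in parse_cigar(res["cigar"]):
                if op in "=XM":
                    for _ in range(length):
                        if gpos == w0:
                            s_start = spos
                        gpos += 1
                        spos += 1
                        if gpos == w1:
                            s_end = spos
                elif op == "I":
                    spos += length
                else:  # deletion in the sequence relative to the gene
                    for _ in range(length):
                        if gpos == w0:
                            s_start = spos
                        gpos += 1
                        if gpos == w1:
                            s_end = spos
        if s_start is None or s_end is None:
            reports.append(WindowReport(sid, covered=False))
            continue
        cut = seq[s_start:s_end]
        trimmed.append((sid, cut))
        reports.append(WindowReport(sid, True, s_start, s_end, len(cut)))
    if not trimmed:
        raise ValueError("no sequence covers the Leray window")
    return trimmed, reports


# ---------------------------------------------------------------------------
# haplotypes and SNP sites


@dataclass
class HaplotypeSummary:
    n_sequences: int
    n_haplotypes: int
    n_segregating_sites: int
    frequencies: dict[str, int]  # haplotype label -> count


def count_haplotypes(seqs: list[tuple[str, str]]) -> HaplotypeSummary:
    """Haplotypes as exact-identity classes (case-folded); strict ambiguity.

    Segregating sites are counted over sequences sharing the modal length
    (length variants are necessarily distinct haplotypes but cannot be
    scored column-wise without an alignment).
    """
    if not seqs:
        raise ValueError("empty dataset")
    upper = [(sid, s.upper()) for sid, s in seqs]
    classes: dict[str, int] = {}
    for _, s in upper:
        classes[s] = classes.get(s, 0) + 1
    ranked = sorted(classes.items(), key=lambda kv: (-kv[1], kv[0]))
    freqs = {f"hap{i + 1}": n for i, (_, n) in enumerate(ranked)}
    lengths = [len(s) for _, s in upper]
    modal_len = max(set(lengths), key=lambda l: (lengths.count(l), -l))
    cohort = [s for _, s in upper if len(s) == modal_len]
    n_seg = 0
    for col in range(modal_len):
        states = {s[col] for s in cohort} & set(DNA)
        if len(states) >= 2:
            n_seg += 1
    return HaplotypeSummary(len(seqs), len(classes), n_seg, freqs)


@dataclass
class SnpMatrix:
    ids: list[str]
    positions: list[int]  # 0-based column coordinates
    matrix: np.ndarray    # (n, L) int8 allele codes; -1 = missing/ambiguous
    n_states: np.ndarray  # states per locus

    @property
    def n_loci(self) -> int:
        return len(self.positions)


def extract_snp_sites(seqs: list[tuple[str, str]]) -> SnpMatrix:
    """Columns with >= 2 unambiguous states, coded as per-locus allele indices."""
    if len({len(s) for _, s in seqs}) > 1:
        raise ValueError("SNP extraction requires equal-length sequences")
    ids = [sid for sid, _ in seqs]
    rows = [s.upper() for _, s in seqs]
    L = len(rows[0]) if rows else 0
    positions, columns, n_states = [], [], []
    for col in range(L):
        states = sorted({s[col] for s in rows} & set(DNA))
        if len(states) >= 2:
            code = {b: i for i, b in enumerate(states)}
            positions.append(col)
            columns.append([code.get(s[col], -1) for s in rows])
            n_states.append(len(states))
    matrix = (
        np.array(columns, dtype=np.int8).T
        if columns
        else np.zeros((len(rows), 0), dtype=np.int8)
    )
    return SnpMatrix(ids, positions, matrix, np.array(n_states, dtype=int))


# ---------------------------------------------------------------------------
# Bayesian estimation of the number of population clusters


@dataclass
class ClusterRunParams:
    n_generations: int = 100_000
    burn_in: int = 200           # discarded *sampled points* of the thinned chain
    thinning: int = 100
    k_max: int = 20
    frequency_model: str = "uncorrelated"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")
        if self.burn_in >= self.n_generations // self.thinning:
            raise ValueError("burn_in must be below the number of retained samples")
        if self.frequency_model not in ("uncorrelated", "correlated"):
            raise ValueError("frequency_model must be 'uncorrelated' or 'correlated'")


@dataclass
class ClusterPosterior:
    posterior: np.ndarray  # mass over K = 1..k_max
    modal_k: int
    modal_density: float
    n_samples: int

    @property
    def reliable(self) -> bool:
        return self.modal_density >= 0.8

    @property
    def low_confidence(self) -> bool:
        return self.modal_density < 0.5

    @classmethod
    def point_mass(cls, k: int, k_max: int) -> "ClusterPosterior":
        post = np.zeros(k_max)
        post[k - 1] = 1.0
        return cls(post, k, 1.0, 0)


from scipy.special import gammaln, logsumexp


def _log_v_weights(n: int, k_max: int, delta: float) -> np.ndarray:
    """log V_n(t) coefficients of the mixture-of-finite-mixtures partition prior.

    With K ~ uniform{1..k_max} components and symmetric Dirichlet(delta)
    weights integrated out, the prior over partitions of n individuals into
    t occupied clusters is V_n(t) * prod_b rising(delta, n_b), where
    V_n(t) = sum_K p(K) K!/(K-t)! / rising(K*delta, n).
    """
    log_v = np.full(k_max + 2, -np.inf)
    for t in range(1, k_max + 1):
        ks = np.arange(t, k_max + 1, dtype=float)
        terms = (
            gammaln(ks + 1)
            - gammaln(ks - t + 1)
            - (gammaln(ks * delta + n) - gammaln(ks * delta))
        )
        log_v[t] = logsumexp(terms) - np.log(k_max)
    return log_v


class _ClusterState:
    """Compact partition state with collapsed Dirichlet allele counts."""

    def __init__(self, X: np.ndarray, n_states: np.ndarray, k_max: int, alpha: float):
        self.n, self.L = X.shape
        self.A = int(n_states.max())
        self.n_states = n_states.astype(float)
        self.alpha = alpha
        self.k_max = k_max
        # per-individual flat indices into the (L, A) count planes
        self.flat = [
            (np.flatnonzero(X[i] >= 0) * self.A + X[i, X[i] >= 0]).astype(np.intp)
            for i in range(self.n)
        ]
        self.li = [np.flatnonzero(X[i] >= 0).astype(np.intp) for i in range(self.n)]
        self.z = np.zeros(self.n, dtype=int)
        self.t = 1
        self.counts = np.zeros((k_max + 1, self.L * self.A))
        self.tot = np.zeros((k_max + 1, self.L))
        self.sizes = np.zeros(k_max + 1, dtype=int)
        for i in range(self.n):
            self._add(i, 0)

    def _add(self, i: int, b: int) -> None:
        self.counts[b, self.flat[i]] += 1
        self.tot[b, self.li[i]] += 1
        self.sizes[b] += 1
        self.z[i] = b

    def _remove(self, i: int) -> int:
        b = self.z[i]
        self.counts[b, self.flat[i]] -= 1
        self.tot[b, self.li[i]] -= 1
        self.sizes[b] -= 1
        return b

    def _drop_block(self, b: int) -> None:
        last = self.t - 1
        if b != last:
            self.counts[b] = self.counts[last]
            self.tot[b] = self.tot[last]
            self.sizes[b] = self.sizes[last]
            self.z[self.z == last] = b
        self.counts[last] = 0
        self.tot[last] = 0
        self.sizes[last] = 0
        self.t -= 1

    def log_pred_one(self, i: int, b: int) -> float:
        """Collapsed predictive log-likelihood of individual i in block b."""
        num = self.counts[b, self.flat[i]] + self.alpha
        den = self.tot[b, self.li[i]] + self.alpha * self.n_states[self.li[i]]
        return float(np.log(num / den).sum())

    def log_pred_all(self, i: int) -> np.ndarray:
        """Predictive log-likelihood of individual i for blocks 0..t-1."""
        num = self.counts[: self.t, self.flat[i]] + self.alpha
        den = self.tot[: self.t][:, self.li[i]] + self.alpha * self.n_states[self.li[i]]
        return np.log(num / den).sum(axis=1)

    def log_marginal(self, b: int) -> float:
        """Collapsed Dirichlet-multinomial log-marginal of block b."""
        c = self.counts[b].reshape(self.L, self.A)
        a = self.alpha
        per_locus = (
            gammaln(a * self.n_states)
            - gammaln(self.tot[b] + a * self.n_states)
            + gammaln(c + a).sum(axis=1)
            - (self.A * gammaln(a))
        )
        return float(per_locus.sum())


def estimate_clusters(snps: SnpMatrix, params: ClusterRunParams | None = None) -> ClusterPosterior:
    """Posterior over the number of population clusters K from SNP loci.

    Collapsed Bayesian mixture with the uncorrelated frequency model:
    per-cluster, per-locus allele frequencies carry a Dirichlet(1) prior and
    are integrated out; mixture weights carry a symmetric Dirichlet(1) prior
    and the number of components a uniform prior up to ``k_max``, yielding an
    exchangeable partition prior (mixture of finite mixtures). The chain
    moves by (a) random-scan collapsed Gibbs reassignment of single
    individuals, which may open or close clusters, and (b) Metropolis
    split/merge moves built by sequential allocation — a split ejects part of
    a cluster into a newborn cluster, a merge is its death — so the sampler
    crosses between K modes that single-site moves cannot. One generation is
    one MCMC move; the number of occupied clusters is sampled every
    ``thinning`` generations and the first ``burn_in`` sampled points are
    discarded. An empty SNP matrix yields a point mass at K = 1 by
    convention; a fixed seed makes the chain reproducible.
    """
    params = params or ClusterRunParams()
    if params.frequency_model == "correlated":
        raise NotImplementedError(
            "only the uncorrelated (conjugate Dirichlet) frequency model is implemented"
        )
    X = snps.matrix
    n, L = X.shape
    if n < 2:
        raise ValueError("need at least two sequences")
    if L == 0:
        return ClusterPosterior.point_mass(1, params.k_max)

    rng = np.random.default_rng(params.seed)
    k_max = min(params.k_max, n)
    delta = 1.0
    log_v = _log_v_weights(n, k_max, delta)
    st = _ClusterState(X, snps.n_states, k_max, alpha=1.0)
    # empty-block predictive per individual: prod_l 1/A_l over observed loci
    log_pred_empty = np.array(
        [-np.log(st.n_states[st.li[i]]).sum() for i in range(n)]
    )

    p_sm = 0.05
    k_samples = []
    unif = rng.random
    for gen in range(1, params.n_generations + 1):
        if unif() < p_sm and n >= 2:
            _split_merge(st, rng, log_v, delta)
        else:
            i = int(rng.integers(n))
            old = st._remove(i)
            if st.sizes[old] == 0:
                st._drop_block(old)
            t = st.t
            logw = np.log(st.sizes[:t] + delta) + st.log_pred_all(i)
            if t < k_max:
                w_new = np.log(delta) + log_v[t + 1] - log_v[t] + log_pred_empty[i]
                logw = np.append(logw, w_new)
            logw -= logw.max()
            w = np.exp(logw)
            cum = np.cumsum(w)
            choice = int(np.searchsorted(cum, unif() * cum[-1]))
            if choice == t:
                st.t += 1
            st._add(i, choice)
        if gen % params.thinning == 0:
            k_samples.append(st.t)

    retained = np.array(k_samples[params.burn_in :])
    post = np.bincount(retained, minlength=params.k_max + 1)[1 : params.k_max + 1].astype(float)
    post /= post.sum()
    modal_k = int(np.argmax(post)) + 1
    return ClusterPosterior(post, modal_k, float(post[modal_k - 1]), len(retained))


def _two_way_alloc_logw(st: "_ClusterState", m: int, b1: int, b2: int, delta: float) -> tuple[float, float]:
    """Normalized log-probabilities of member m joining block b1 vs b2."""
    l1 = np.log(st.sizes[b1] + delta) + st.log_pred_one(m, b1)
    l2 = np.log(st.sizes[b2] + delta) + st.log_pred_one(m, b2)
    hi = max(l1, l2)
    lse = hi + np.log(np.exp(l1 - hi) + np.exp(l2 - hi))
    return l1 - lse, l2 - lse


def _split_merge(st: _ClusterState, rng: np.random.Generator, log_v: np.ndarray, delta: float) -> None:
    """Sequentially-allocated split/merge Metropolis move on the partition."""
    n = st.n
    i, j = rng.choice(n, size=2, replace=False)
    ci, cj = st.z[i], st.z[j]
    if ci == cj:
        if st.t >= st.k_max:
            return
        members = [m for m in np.flatnonzero(st.z == ci) if m not in (i, j)]
        old_logm = st.log_marginal(ci)
        n_c = st.sizes[ci]
        # eject the block into its anchor i (stays in ci) and a scratch block
        # anchored at j; allocate the rest sequentially in random order
        scratch = st.t  # capacity is k_max + 1, so always addressable
        for m in [j] + members:
            st._remove(m)
        st._add(j, scratch)
        log_q = 0.0
        for idx in rng.permutation(len(members)):
            m = members[idx]
            lw1, lw2 = _two_way_alloc_logw(st, m, ci, scratch, delta)
            if np.log(rng.random()) < lw1:
                log_q += lw1
                st._add(m, ci)
            else:
                log_q += lw2
                st._add(m, scratch)
        n1, n2 = st.sizes[ci], st.sizes[scratch]
        delta_log = (
            st.log_marginal(ci) + st.log_marginal(scratch) - old_logm
            + log_v[st.t + 1] - log_v[st.t]
            + gammaln(n1 + delta) + gammaln(n2 + delta)
            - gammaln(n_c + delta) - gammaln(delta)
            - log_q
        )
        if np.log(rng.random()) < delta_log:
            st.t += 1  # scratch becomes a real block
        else:  # undo: fold scratch back into ci
            for m in np.flatnonzero(st.z == scratch):
                st._remove(m)
                st._add(m, ci)
    else:
        if st.t < 2:
            return
        members = [
            m for m in np.flatnonzero((st.z == ci) | (st.z == cj)) if m not in (i, j)
        ]
        logm_ci = st.log_marginal(ci)
        logm_cj = st.log_marginal(cj)
        n1, n2 = st.sizes[ci], st.sizes[cj]
        # reverse-split probability: sequentially reallocate members to their
        # actual blocks, starting from the anchors alone
        saved_z = st.z[members].copy() if members else np.array([], dtype=int)
        for m in members:
            st._remove(m)
        log_q = 0.0
        for idx in rng.permutation(len(members)):
            m = members[idx]
            lw1, lw2 = _two_way_alloc_logw(st, m, ci, cj, delta)
            if saved_z[idx] == ci:
                log_q += lw1
                st._add(m, ci)
            else:
                log_q += lw2
                st._add(m, cj)
        # propose the merge: everything from cj into ci
        delta_log = (
            -logm_ci - logm_cj
            + log_v[st.t - 1] - log_v[st.t]
            + gammaln(n1 + n2 + delta) + gammaln(delta)
            - gammaln(n1 + delta) - gammaln(n2 + delta)
            + log_q
        )
        cj_members = np.flatnonzero(st.z == cj)
        for m in cj_members:
            st._remove(m)
            st._add(m, ci)
        delta_log += st.log_marginal(ci)
        if np.log(rng.random()) < delta_log:
            st._drop_block(cj)
        else:  # undo the merge
            for m in cj_members:
                st._remove(m)
                st._add(m, cj)


# ---------------------------------------------------------------------------
# the fragment comparison


def wilcoxon_signed_rank(
    differences: list[float] | np.ndarray, exact_max_n: int = 12
) -> tuple[float, float, int]:
    """One-tailed signed-rank test for a positive median difference.

    Returns (W, p, n_nonzero) with W the positive-rank sum. Zero differences
    are dropped; ties get average ranks. The null is enumerated exactly over
    all 2^n sign patterns for n <= exact_max_n; otherwise the normal
    approximation with tie correction and continuity correction is used.
    No nonzero differences -> p = 1 by convention.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 0.0, 1.0, 0
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if n <= exact_max_n:
        ge = 0
        for mask in range(1 << n):
            w = sum(ranks[i] for i in range(n) if mask >> i & 1)
            if w >= w_pos - 1e-12:
                ge += 1
        return w_pos, ge / (1 << n), n
    mu = n * (n + 1) / 4
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - (tie_counts**3 - tie_counts).sum() / 48
    zstat = (w_pos - mu - 0.5) / np.sqrt(var)
    return w_pos, float(stats.norm.sf(zstat)), n


@dataclass
class ComparisonReport:
    n: int
    n_nonzero: int
    w_statistic: float
    p_value: float
    mean_original: float
    mean_trimmed: float
    corr_nseq_k: tuple[float, float] = (np.nan, np.nan)   # (r, p)
    corr_length_k: tuple[float, float] = (np.nan, np.nan)
    pairs: list[tuple[str, int, int]] = field(default_factory=list)


def compare_fragments(
    pairs: list[tuple[str, int, int]],
    n_sequences: list[int] | None = None,
    lengths: list[int] | None = None,
) -> ComparisonReport:
    """Paired comparison of cluster counts: (dataset_id, original K, trimmed K).

    Tests the one-sided alternative that trimming to the Leray window lowers
    the number of detectable clusters; optional per-dataset sequence counts
    and original lengths give the product-moment correlations with K.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two paired datasets")
    orig = np.array([o for _, o, _ in pairs], dtype=float)
    trim = np.array([t for _, _, t in pairs], dtype=float)
    w, p, n_nonzero = wilcoxon_signed_rank(orig - trim)
    report = ComparisonReport(
        n=len(pairs),
        n_nonzero=n_nonzero,
        w_statistic=w,
        p_value=p,
        mean_original=float(orig.mean()),
        mean_trimmed=float(trim.mean()),
        pairs=list(pairs),
    )
    def _corr(x: np.ndarray) -> tuple[float, float]:
        if np.std(x) == 0 or np.std(orig) == 0:  # correlation undefined
            return (np.nan, np.nan)
        r, pv = stats.pearsonr(x, orig)
        return (float(r), float(pv))

    if n_sequences is not None:
        report.corr_nseq_k = _corr(np.asarray(n_sequences, dtype=float))
    if lengths is not None:
        report.corr_length_k = _corr(np.asarray(lengths, dtype=float))
    return report
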