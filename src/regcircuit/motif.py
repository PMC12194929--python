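"""Position weight matrices, Markov backgrounds, exact-p-value scanning and
ZOOPS motif discovery.

The scanner scores log-odds in bits against the 0-order marginal of the
background and converts scores to p-values with an exact dynamic program
over a discretized score lattice (granularity ``epsilon`` bits), the same
construction FIMO uses.  Discovery is an expectation-maximization fit of the
ZOOPS model (zero or one site per sequence), seeded from over-represented
words, with sequential discovery via probabilistic site erasure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Sequence

import numpy as np

from .io_formats import SequenceRecord, reverse_complement

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_ENCODE = np.full(256, -1, dtype=np.int64)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i

LN2 = math.log(2.0)


def encode(seq: str) -> np.ndarray:
    """Map a nucleotide string to indices 0..3; anything else (N) becomes -1."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# PWM


@dataclass
class PWM:
    """Per-column base probabilities of a binding motif.

    ``matrix`` has shape (width, 4) with columns ordered A, C, G, T; every
    row (motif column) sums to 1 within 1e-9.
    """

    motif_id: str
    matrix: np.ndarray
    nsites: int = 0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError(f"motif {self.motif_id}: matrix must be (width, 4)")
        if self.matrix.shape[0] < 1:
            raise ValueError(f"motif {self.motif_id}: zero-width matrix")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValueError(f"motif {self.motif_id}: columns must sum to 1")
        if np.any(self.matrix < 0):
            raise ValueError(f"motif {self.motif_id}: negative probabilities")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.motif_id, self.matrix[::-1, ::-1], self.nsites)


def build_pwm_from_sites(sites: Sequence[str], alpha: float = 0.0,
                         q: np.ndarray | None = None,
                         motif_id: str = "motif") -> PWM:
    """Build a PWM from aligned equal-length sites.

    Column j probability of base b is ``(count_j(b) + alpha*q_b) / (n + alpha)``
    with q uniform by default.
    """
    if not sites:
        raise ValueError("cannot build a PWM from zero sites")
    width = len(sites[0])
    if any(len(s) != width for s in sites):
        raise ValueError("aligned sites must all have the same length")
    q = np.full(4, 0.25) if q is None else np.asarray(q, dtype=float)
    counts = np.zeros((width, 4))
    for s in sites:
        idx = encode(s.upper())
        if np.any(idx < 0):
            raise ValueError(f"site {s!r} contains characters outside ACGT")
        counts[np.arange(width), idx] += 1.0
    n = len(sites)
    matrix = (counts + alpha * q) / (n + alpha)
    return PWM(motif_id=motif_id, matrix=matrix, nsites=n)


def information_content(pwm: PWM, nsites: int | None = None) -> np.ndarray:
    """Schneider–Stephens per-column information Rseq in bits.

    Rseq(j) = 2 - (H_j + e(n)) with small-sample correction
    e(n) = 3 / (2 ln 2 n); negative values are clipped to 0.
    """
    n = pwm.nsites if nsites is None else nsites
    if n < 1:
        raise ValueError("information content needs nsites >= 1")
    f = pwm.matrix
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
    entropy = -terms.sum(axis=1)
    e_n = 3.0 / (2.0 * LN2 * n)
    return np.clip(2.0 - (entropy + e_n), 0.0, None)


# ---------------------------------------------------------------------------
# Markov background


@dataclass
class MarkovBackground:
    """Order-k conditional base distributions.

    ``probs`` maps every context string of length 0..k to a length-4
    probability vector; contexts shorter than k serve the first k positions
    of a sequence.
    """

    order: int
    probs: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if not 0 <= self.order <= 4:
            raise ValueError("background order must be in [0, 4]")
        for length in range(self.order + 1):
            for ctx in ("".join(p) for p in product(ALPHABET, repeat=length)):
                if ctx not in self.probs:
                    raise ValueError(f"missing context {ctx!r} of length {length}")
                v = np.asarray(self.probs[ctx], dtype=float)
                if abs(v.sum() - 1.0) > 1e-9:
                    raise ValueError(f"context {ctx!r}: probabilities must sum to 1")
                self.probs[ctx] = v

    @classmethod
    def uniform(cls, order: int = 0) -> "MarkovBackground":
        probs = {
            "".join(p): np.full(4, 0.25)
            for length in range(order + 1)
            for p in product(ALPHABET, repeat=length)
        }
        return cls(order=order, probs=probs)

    @property
    def marginal(self) -> np.ndarray:
        """Stationary 0-order letter distribution (the empty-context entry)."""
        return self.probs[""]

    def sample(self, length: int, rng: np.random.Generator) -> str:
        if length < self.order:
            raise ValueError(f"length {length} < background order {self.order}")
        if self.order == 0:
            cdf = np.cumsum(self.marginal)
            idx = np.searchsorted(cdf, rng.random(length), side="right")
            return "".join(ALPHABET[i] for i in np.minimum(idx, 3))
        cdfs = {ctx: np.cumsum(p) for ctx, p in self.probs.items()}
        u = rng.random(length)
        out: list[str] = []
        for i in range(length):
            ctx = "".join(out[max(0, i - self.order):i])
            b = int(np.searchsorted(cdfs[ctx], u[i], side="right"))
            out.append(ALPHABET[min(b, 3)])
        return "".join(out)

    def position_logprobs(self, idx: np.ndarray, seq: str) -> np.ndarray:
        """Natural-log conditional probability of each position of a sequence
        under this model; N positions get -inf."""
        n = len(seq)
        out = np.full(n, -np.inf)
        for i in range(n):
            if idx[i] < 0:
                continue
            lo = max(0, i - self.order)
            if np.any(idx[lo:i] < 0):
                ctx = ""
            else:
                ctx = seq[lo:i]
            out[i] = math.log(self.probs[ctx][idx[i]])
        return out


def train_markov_background(sequences: Iterable[str | SequenceRecord],
                            order: int) -> MarkovBackground:
    """Estimate an order-k background from (k+1)-mer counts with add-one
    smoothing; windows containing N are skipped.  Conditionals for every
    context length 0..k are fitted so sequence starts are covered.
    """
    if not 0 <= order <= 4:
        raise ValueError("background order must be in [0, 4]")
    seqs = [s.sequence if isinstance(s, SequenceRecord) else s for s in sequences]
    usable = sum(len(s) for s in seqs)
    if usable <= order:
        raise ValueError("not enough sequence to train the requested order")
    probs: dict[str, np.ndarray] = {}
    for length in range(order + 1):
        counts = {"".join(p): np.ones(4) for p in product(ALPHABET, repeat=length)}
        for s in seqs:
            idx = encode(s)
            for i in range(length, len(s)):
                window = idx[i - length:i + 1]
                if np.any(window < 0):
                    continue
                counts[s[i - length:i]][idx[i]] += 1.0
        for ctx, c in counts.items():
            probs[ctx] = c / c.sum()
    return MarkovBackground(order=order, probs=probs)


def sample_background_sequence(background: MarkovBackground, length: int,
                               seed: int | np.random.Generator) -> str:
    """Draw a sequence from the background model; deterministic given seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return background.sample(length, rng)


# ---------------------------------------------------------------------------
# Log-odds scoring and the exact p-value dynamic program


def log_odds(pwm: PWM, background: MarkovBackground) -> np.ndarray:
    """(width, 4) log2 odds against the background's 0-order marginal.

    Zero probabilities yield -inf entries; scanning requires a strictly
    positive (pseudocounted) matrix."""
    q0 = background.marginal
    with np.errstate(divide="ignore"):
        return np.log2(pwm.matrix / q0)


@dataclass
class ScoreDistribution:
    """Exact null distribution of the discretized log-odds score.

    Scores are integers in units of ``epsilon`` bits.  ``sf[i]`` is
    P(score >= min_total + i) under the background marginal with positional
    independence.
    """

    epsilon: float
    int_matrix: np.ndarray  # (width, 4) integer scores
    min_total: int
    sf: np.ndarray

    def pvalue_int(self, int_score: int) -> float:
        i = int_score - self.min_total
        if i <= 0:
            return 1.0
        if i >= len(self.sf):
            return float(self.sf[-1])
        return float(self.sf[i])

    def pvalue(self, score_bits: float) -> float:
        return self.pvalue_int(int(round(score_bits / self.epsilon)))


def score_pvalue_table(pwm: PWM, background: MarkovBackground,
                       epsilon: float = 1e-3) -> ScoreDistribution:
    """Exact score -> p-value mapping by dynamic programming over columns."""
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if np.any(pwm.matrix <= 0):
        raise ValueError(
            f"motif {pwm.motif_id}: zero probabilities; apply a pseudocount "
            "before scanning")
    lo = log_odds(pwm, background)
    int_matrix = np.rint(lo / epsilon).astype(np.int64)
    q0 = background.marginal
    mins = int_matrix.min(axis=1)
    maxs = int_matrix.max(axis=1)
    span = int((maxs - mins).sum()) + 1
    pdf = np.zeros(span)
    pdf[0] = 1.0
    filled = 1
    for j in range(pwm.width):
        new = np.zeros(span)
        col = int_matrix[j] - mins[j]
        width_j = int(maxs[j] - mins[j])
        for b in range(4):
            off = int(col[b])
            new[off:off + filled] += q0[b] * pdf[:filled]
        filled += width_j
        pdf = new
    # survival function: P(score >= min_total + i)
    sf = np.minimum(np.cumsum(pdf[::-1])[::-1], 1.0)
    return ScoreDistribution(epsilon=epsilon, int_matrix=int_matrix,
                             min_total=int(mins.sum()), sf=sf)


@dataclass
class SiteHit:
    seq_id: str
    start: int  # 1-based inclusive within the scanned sequence
    end: int
    strand: str
    score: float  # log-odds, bits
    pvalue: float
    motif_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _window_int_scores(idx: np.ndarray, int_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Integer scores for every window; second array flags windows without N."""
    width = int_matrix.shape[0]
    n = len(idx)
    if n < width:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=bool)
    windows = np.lib.stride_tricks.sliding_window_view(idx, width)
    valid = np.all(windows >= 0, axis=1)
    safe = np.where(windows >= 0, windows, 0)
    scores = int_matrix[np.arange(width), safe].sum(axis=1)
    return scores, valid


def scan_sequences(pwm: PWM, sequences: Iterable[SequenceRecord | tuple[str, str]],
                   background: MarkovBackground, p_max: float = 1e-4,
                   both_strands: bool = True, epsilon: float = 1e-3,
                   table: ScoreDistribution | None = None) -> list[SiteHit]:
    """Scan sequences on both strands; windows containing N are skipped and
    hits with p < p_max are returned sorted by (seq_id, start, strand)."""
    if not 0 < p_max <= 1:
        raise ValueError("p_max must be in (0, 1]")
    if table is None:
        table = score_pvalue_table(pwm, background, epsilon)
    width = pwm.width
    hits: list[SiteHit] = []
    for rec in sequences:
        seq_id, seq = (rec.id, rec.sequence) if isinstance(rec, SequenceRecord) else rec
        idx = encode(seq)
        n = len(seq)
        strands = [("+", idx)]
        if both_strands:
            strands.append(("-", encode(reverse_complement(seq))))
        for strand, sidx in strands:
            scores, valid = _window_int_scores(sidx, table.int_matrix)
            for pos in np.nonzero(valid)[0]:
                p = table.pvalue_int(int(scores[pos]))
                if p < p_max:
                    if strand == "+":
                        start = int(pos) + 1
                    else:
                        start = n - int(pos) - width + 1
                    hits.append(SiteHit(
                        seq_id=seq_id, start=start, end=start + width - 1,
                        strand=strand, score=float(scores[pos]) * table.epsilon,
                        pvalue=p, motif_id=pwm.motif_id))
    hits.sort(key=lambda h: (h.seq_id, h.start, h.strand))
    return hits


def filter_overlaps(hits: Sequence[SiteHit]) -> list[SiteHit]:
    """Greedy best-score overlap filter, applied per sequence.

    A hit is retained iff it overlaps no already-retained hit by more than
    50% of the shorter hit's length.  Ties break on smaller p, then leftmost
    start.  Idempotent and invariant to input order.
    """
    by_seq: dict[str, list[SiteHit]] = {}
    for h in hits:
        by_seq.setdefault(h.seq_id, []).append(h)
    out: list[SiteHit] = []
    for seq_id in sorted(by_seq):
        ranked = sorted(by_seq[seq_id],
                        key=lambda h: (-h.score, h.pvalue, h.start, h.strand))
        kept: list[SiteHit] = []
        for h in ranked:
            ok = True
            for k in kept:
                overlap = min(h.end, k.end) - max(h.start, k.start) + 1
                if overlap > 0.5 * min(h.length, k.length):
                    ok = False
                    break
            if ok:
                kept.append(h)
        out.extend(sorted(kept, key=lambda h: (h.start, h.strand)))
    return out


# ---------------------------------------------------------------------------
# ZOOPS EM discovery


@dataclass
class DiscoveredMotif:
    pwm: PWM
    gamma_hat: float
    objective: float  # final relative log-likelihood
    loglik_trace: list[float] = field(default_factory=list)
    site_posteriors: dict[str, float] = field(default_factory=dict)
    score: float = 0.0  # selection objective: per-site IC x expected sites

    @property
    def consensus(self) -> str:
        return self.pwm.consensus


class _SeqData:
    """Per-sequence precomputation shared by all EM runs."""

    def __init__(self, seq_id: str, seq: str, background: MarkovBackground):
        self.seq_id = seq_id
        self.seq = seq
        self.idx = encode(seq)
        rc = reverse_complement(seq)
        self.idx_rc = encode(rc)
        self.bg_fwd = background.position_logprobs(self.idx, seq)
        self.bg_rev = background.position_logprobs(self.idx_rc, rc)
        self.erase = np.ones(len(seq))  # per-position erasure weight

    def windows(self, width: int):
        """Window index matrices, background window log-probs and erasure
        factors for both strands, concatenated (fwd then rc)."""
        n = len(self.seq)
        m = n - width + 1
        if m < 1:
            return None
        win_f = np.lib.stride_tricks.sliding_window_view(self.idx, width)
        win_r = np.lib.stride_tricks.sliding_window_view(self.idx_rc, width)
        bg_f = np.lib.stride_tricks.sliding_window_view(self.bg_fwd, width).sum(axis=1)
        bg_r = np.lib.stride_tricks.sliding_window_view(self.bg_rev, width).sum(axis=1)
        er = np.lib.stride_tricks.sliding_window_view(self.erase, width).prod(axis=1)
        valid_f = np.all(win_f >= 0, axis=1)
        valid_r = np.all(win_r >= 0, axis=1)
        windows = np.vstack([np.where(win_f >= 0, win_f, 0),
                             np.where(win_r >= 0, win_r, 0)])
        bg = np.concatenate([bg_f, bg_r])
        # reverse-strand window starting at rc position j covers forward
        # positions n-j-width .. n-j-1; erasure follows the covered letters
        er_r = er[::-1] if width == 1 else np.lib.stride_tricks.sliding_window_view(
            self.erase[::-1], width).prod(axis=1)
        erf = np.concatenate([er, er_r])
        valid = np.concatenate([valid_f, valid_r])
        return windows, bg, erf, valid, m


def _zoops_em(data: list[_SeqData], width: int, seed_pwm: np.ndarray,
              gamma0: float, pseudocount: float, tol: float,
              max_iter: int) -> DiscoveredMotif | None:
    mat = seed_pwm.copy()
    gamma = gamma0
    trace: list[float] = []
    pre = []
    for d in data:
        w = d.windows(width)
        if w is not None:
            pre.append((d, *w))
    if not pre:
        return None
    n_seq = len(pre)
    arange_w = np.arange(width)
    z_store: list[np.ndarray] = []
    prior_c = pseudocount * 0.25  # Dirichlet exponent matching the M-step
    for _ in range(max_iter):
        counts = np.zeros((width, 4))
        q_sum = 0.0
        z_store = []
        log_mat = np.log(mat)
        # penalized (MAP) objective: the quantity this EM monotonically
        # increases, given the pseudocounted M-step
        ll = prior_c * float(log_mat.sum())
        for d, windows, bg, erf, valid, m in pre:
            site_ll = log_mat[arange_w, windows].sum(axis=1)
            with np.errstate(divide="ignore"):
                log_r = site_ll - bg + np.log(np.where(erf > 0, erf, 1e-300))
            log_r[~valid] = -np.inf
            prior = gamma / (2.0 * m)
            w_pos = np.where(valid, prior * np.exp(np.clip(log_r, -700, 700)), 0.0)
            denom = (1.0 - gamma) + w_pos.sum()
            z = w_pos / denom
            z_store.append(z)
            q_sum += z.sum()
            ll += math.log(denom)
            onehot = np.zeros((len(z), width, 4))
            onehot[np.arange(len(z))[:, None], arange_w, windows] = z[:, None]
            counts += onehot.sum(axis=0)
        trace.append(ll)
        new_gamma = min(max(q_sum / n_seq, 1e-6), 1.0 - 1e-6)
        denom_c = counts.sum(axis=1, keepdims=True) + pseudocount
        new_mat = (counts + pseudocount * 0.25) / denom_c
        if len(trace) > 1 and trace[-1] - trace[-2] < tol:
            mat, gamma = new_mat, new_gamma
            break
        mat, gamma = new_mat, new_gamma
    posteriors = {d.seq_id: float(z.sum()) for (d, *_), z in zip(pre, z_store)}
    pwm = PWM(motif_id=f"w{width}", matrix=mat,
              nsites=max(1, int(round(gamma * n_seq))))
    dm = DiscoveredMotif(pwm=pwm, gamma_hat=gamma, objective=trace[-1],
                         loglik_trace=trace, site_posteriors=posteriors)
    dm._z = [(d, z) for (d, *_), z in zip(pre, z_store)]  # for erasure
    return dm


def _seed_words(data: list[_SeqData], width: int, background: MarkovBackground,
                n_seeds: int) -> list[str]:
    """Most over-represented width-mers (count over background expectation)."""
    counts: dict[str, int] = {}
    total = 0
    q0 = background.marginal
    for d in data:
        for seq in (d.seq, reverse_complement(d.seq)):
            for i in range(len(seq) - width + 1):
                w = seq[i:i + width]
                if "N" in w:
                    continue
                counts[w] = counts.get(w, 0) + 1
                total += 1
    if not counts:
        return []

    def expectation(word: str) -> float:
        p = 1.0
        for ch in word:
            p *= q0[BASE_INDEX[ch]]
        return total * p

    ranked = sorted(counts.items(),
                    key=lambda kv: (-(kv[1] / expectation(kv[0])), kv[0]))
    seeds = [w for w, c in ranked if c >= 2][:n_seeds]
    if len(seeds) < n_seeds:
        extra = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        for w, _ in extra:
            if w not in seeds:
                seeds.append(w)
            if len(seeds) == n_seeds:
                break
    return seeds


def discover_motifs_zoops(sequences: Sequence[SequenceRecord | tuple[str, str]],
                          widths: Iterable[int] = range(5, 21),
                          n_motifs: int = 1,
                          background: MarkovBackground | None = None,
                          seed: int = 0, n_seeds: int = 5,
                          pseudocount: float = 0.01, tol: float = 1e-6,
                          max_iter: int = 200) -> list[DiscoveredMotif]:
    """Sequential ZOOPS EM motif discovery.

    For every width, candidate PWMs are seeded from the ``n_seeds`` most
    over-represented words (seed base probability 0.7) and refined by EM.
    The motif with the highest per-site information content times expected
    site count wins; its sites are probabilistically erased before the next
    round.  Deterministic given ``seed``.
    """
    seqs = [(r.id, r.sequence) if isinstance(r, SequenceRecord) else tuple(r)
            for r in sequences]
    if len(seqs) < 2:
        raise ValueError("discovery needs at least 2 sequences")
    widths = sorted(set(int(w) for w in widths))
    if background is None:
        background = train_markov_background([s for _, s in seqs], order=0)
    usable_widths = [w for w in widths if any(len(s) >= w for _, s in seqs)]
    if not usable_widths:
        raise ValueError("no sequence is long enough for any requested width")
    data = [_SeqData(sid, s, background) for sid, s in seqs]
    found: list[DiscoveredMotif] = []
    for round_no in range(n_motifs):
        best: DiscoveredMotif | None = None
        for width in usable_widths:
            for word in _seed_words(data, width, background, n_seeds):
                seed_mat = np.full((width, 4), 0.1)
                for j, ch in enumerate(word):
                    seed_mat[j] = 0.1
                    seed_mat[j, BASE_INDEX[ch]] = 0.7
                dm = _zoops_em(data, width, seed_mat, gamma0=0.5,
                               pseudocount=pseudocount, tol=tol,
                               max_iter=max_iter)
                if dm is None:
                    continue
                exp_sites = dm.gamma_hat * len(data)
                ic = information_content(dm.pwm, nsites=max(1, int(round(exp_sites)))).sum()
                dm.score = ic * exp_sites
                if best is None or dm.score > best.score:
                    best = dm
        if best is None:
            break
        best.pwm.motif_id = f"motif_{round_no + 1}"
        found.append(best)
        # probabilistic erasure: down-weight letters by (1 - site posterior)
        for d, z in best._z:
            width = best.pwm.width
            n = len(d.seq)
            m = n - width + 1
            for pos, zp in enumerate(z):
                if zp <= 0:
                    continue
                if pos < m:  # forward strand window
                    d.erase[pos:pos + width] *= (1.0 - zp)
                else:  # rc window starting at rc index pos - m
                    j = pos - m
                    d.erase[n - j - width:n - j] *= (1.0 - zp)
        del best._z
    return found


def align_pwms(a: PWM, b: PWM, min_overlap: int = 4) -> tuple[float, int, str]:
    """Best mean per-column Pearson correlation between two PWMs over all
    offsets and strands.  Returns (mean_r, offset, strand)."""

    def col_r(x: np.ndarray, y: np.ndarray) -> float:
        xc, yc = x - x.mean(), y - y.mean()
        d = math.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        return float((xc * yc).sum() / d) if d > 0 else 0.0

    best = (-2.0, 0, "+")
    for strand, mb in (("+", b.matrix), ("-", b.matrix[::-1, ::-1])):
        wa, wb = a.width, mb.shape[0]
        for off in range(-(wb - min_overlap), wa - min_overlap + 1):
            cols = [(a.matrix[i], mb[i - off])
                    for i in range(max(0, off), min(wa, wb + off))]
            if len(cols) < min_overlap:
                continue
            r = float(np.mean([col_r(x, y) for x, y in cols]))
            if r > best[0]:
                best = (r, off, strand)
    return best
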