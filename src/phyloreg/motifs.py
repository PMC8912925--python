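"""PWM motif scanning and block-wise pairwise subfamily enrichment.

The scanner scores log2-odds against a background base composition on
both strands; enrichment uses ZOOPS counting (a sequence is a hit if it
contains at least one match) with a one-sided hypergeometric test of
target hits against the pooled target+background sequence set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .phylo import Alignment

_IDX = {b: i for i, b in enumerate("ACGT")}
_COMP = str.maketrans("ACGTN", "TGCAN")


class MotifError(ValueError):
    pass


@dataclass
class PWM:
    name: str
    matrix: np.ndarray  # positions x {A,C,G,T} probabilities
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    score_frac: float = 0.80  # threshold as fraction of maximal score
    pseudocount: float = 1e-3

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise MotifError("PWM matrix must be positions x 4")
        rowsum = self.matrix.sum(axis=1)
        if not np.allclose(rowsum, 1.0, atol=1e-6):
            self.matrix = self.matrix / rowsum[:, None]

    def __len__(self):
        return self.matrix.shape[0]

    @property
    def logodds(self) -> np.ndarray:
        p = self.matrix + self.pseudocount
        p = p / p.sum(axis=1)[:, None]
        return np.log2(p / self.background)

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=1).sum())

    @property
    def threshold(self) -> float:
        return self.score_frac * self.max_score

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name + "_rc", self.matrix[::-1, ::-1],
                   self.background[::-1], self.score_frac, self.pseudocount)

    @classmethod
    def from_consensus(cls, name: str, motif: str, identity: float = 0.997) -> "PWM":
        """Near-deterministic PWM for a literal motif string."""
        L = len(motif)
        mat = np.full((L, 4), (1 - identity) / 3)
        for i, ch in enumerate(motif.upper()):
            if ch not in _IDX:
                raise MotifError(f"bad base {ch!r} in motif")
            mat[i, _IDX[ch]] = identity
        return cls(name, mat)


def read_jaspar(path) -> list[PWM]:
    """JASPAR-style count matrices; counts get pseudocount 0.5."""
    pwms = []
    name, rows = None, {}
    with open(path) as fh:
        lines = list(fh) + [">__end__\n"]
    for line in lines:
        line = line.strip()
        if line.startswith(">"):
            if name is not None and rows:
                mat = np.array([rows[b] for b in "ACGT"]).T + 0.5
                pwms.append(PWM(name, mat / mat.sum(axis=1)[:, None]))
            name, rows = line[1:].split()[0], {}
        elif line:
            base = line[0].upper()
            nums = line[line.index("[") + 1 : line.index("]")] if "[" in line else line[1:]
            rows[base] = [float(x) for x in nums.split()]
    if not pwms:
        raise MotifError(f"no JASPAR matrices in {path}")
    return pwms


def read_homer(path) -> list[PWM]:
    """HOMER ``>consensus name threshold`` probability-row format."""
    pwms = []
    name, rows = None, []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh] + [">"]
    for line in lines:
        if line.startswith(">"):
            if name is not None and rows:
                pwms.append(PWM(name, np.array(rows)))
            parts = line[1:].split()
            name = parts[1] if len(parts) > 1 else (parts[0] if parts else None)
            rows = []
        elif line:
            rows.append([float(x) for x in line.split()[:4]])
    if not pwms:
        raise MotifError(f"no HOMER matrices in {path}")
    return pwms


def scan_pwm(sequence: str, pwm: PWM) -> list[tuple[int, str, float]]:
    """Hits (position, strand, score) with score >= the PWM threshold.

    Both strands are scanned; positions are forward-strand 0-based window
    starts.  Windows containing N (or any non-ACGT symbol) are skipped.
    """
    seq = sequence.upper().replace("-", "")
    L, m = len(seq), len(pwm)
    if m > L:
        return []
    codes = np.full(L, -1, dtype=np.int8)
    for b, i in _IDX.items():
        codes[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(b)] = i
    lods = {"+": pwm.logodds, "-": pwm.reverse_complement().logodds}
    n_win = L - m + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, m)
    ok = (windows >= 0).all(axis=1)
    hits = []
    for strand in "+-":
        lo = lods[strand]
        scores = np.where(
            ok, lo[np.arange(m)[None, :], np.clip(windows, 0, 3)].sum(axis=1), -np.inf
        )
        for pos in np.flatnonzero(scores >= pwm.threshold):
            hits.append((int(pos), strand, float(scores[pos])))
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


@dataclass
class MotifEnrichment:
    motif: str
    block: str
    target: str
    background: str
    n_target_hit: int
    n_target: int
    n_bg_hit: int
    n_bg: int
    p: float
    passes_cutoff: bool


def _zoops(seqs, pwm: PWM) -> int:
    return sum(1 for s in seqs if scan_pwm(s, pwm))


def block_enrichment(
    block_slices_by_subfamily: dict,
    pwms: list[PWM],
    target: str | None = None,
    background: str | None = None,
    cutoff: float = 1e-5,
    min_seqs: int = 5,
) -> list[MotifEnrichment]:
    """ZOOPS hypergeometric motif enrichment per (motif, block, pair).

    ``block_slices_by_subfamily``: subfamily -> block name -> Alignment
    (or list of sequences); gaps are stripped before scanning.  With
    ``target``/``background`` unset, every ordered subfamily pair is
    tested within every block.
    """
    fams = sorted(block_slices_by_subfamily)
    pairs = (
        [(target, background)]
        if target and background
        else [(t, b) for t in fams for b in fams if t != b]
    )
    results = []
    for t, b in pairs:
        blocks_t = block_slices_by_subfamily[t]
        blocks_b = block_slices_by_subfamily[b]
        for block in sorted(set(blocks_t) & set(blocks_b)):
            seqs_t = _degapped(blocks_t[block])
            seqs_b = _degapped(blocks_b[block])
            if len(seqs_t) < min_seqs or len(seqs_b) < min_seqs:
                continue
            for pwm in pwms:
                k_t = _zoops(seqs_t, pwm)
                k_b = _zoops(seqs_b, pwm)
                n_t, n_b = len(seqs_t), len(seqs_b)
                K = k_t + k_b
                if K == 0 or K == n_t + n_b:
                    p = 1.0
                else:
                    # P(X >= k_t) drawing n_t from pooled population
                    p = float(stats.hypergeom.sf(k_t - 1, n_t + n_b, K, n_t))
                results.append(
                    MotifEnrichment(pwm.name, block, t, b, k_t, n_t, k_b, n_b,
                                    p, p <= cutoff)
                )
    results.sort(key=lambda r: (r.p, r.motif, r.block, r.target))
    return results


def _degapped(block) -> list[str]:
    rows = block.rows if isinstance(block, Alignment) else list(block)
    return [r.replace("-", "") for r in rows]


def find_subfamily_specific_insertions(
    consensus_aln: Alignment, target: str, others: list[str]
) -> list[tuple[int, str]]:
    """Maximal column runs where the target has bases and all others gaps.

    Returned positions are coordinates in the target's *ungapped*
    sequence (position of the run start).
    """
    idx = {t: i for i, t in enumerate(consensus_aln.ids)}
    trow = consensus_aln.rows[idx[target]]
    orows = [consensus_aln.rows[idx[o]] for o in others]
    runs = []
    cur = None
    tpos = 0
    for col, ch in enumerate(trow):
        specific = ch not in "-" and all(r[col] == "-" for r in orows)
        if specific:
            if cur is None:
                cur = [tpos, []]
            cur[1].append(ch)
        elif cur is not None:
            runs.append((cur[0], "".join(cur[1])))
            cur = None
        if ch != "-":
            tpos += 1
    if cur is not None:
        runs.append((cur[0], "".join(cur[1])))
    return runs
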