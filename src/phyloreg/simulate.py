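"""Synthetic LTR-family generator with known ground truth.

The model: a single ancestral LTR spawns subfamily founders along a random
backbone tree (substitutions only, so founder coordinates stay in the
ancestor frame); optional founder-level events — inter-lineage block
recombination, one tandem block duplication, a planted motif insertion —
are applied before each founder emits a star burst of copies with
exponential terminal branch lengths, per-copy substitutions and indels.
Regulatory marks are subfamily-conditional Bernoulli draws; insertion ages
are uniform within each subfamily's activity window, and orthologous
presence across a species tree follows directly from age vs. split time.

Because every indel is tracked, the generator emits the exact multiple
sequence alignment of the family alongside the ungapped sequences.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import seqio
from .phylo import Alignment
from .recomb import BlockDefinition

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_GAP = ord("-")

# default three waves of transpositional activity (mya), oldest first
_DEFAULT_WINDOWS = [(40.0, 25.0), (20.0, 9.0), (10.0, 4.0)]
# approximate divergence times of primate outgroups from human (mya)
DEFAULT_SPECIES_SPLITS = {
    "chimp": 6.0,
    "gorilla": 9.0,
    "orangutan": 16.0,
    "gibbon": 20.0,
    "macaque": 25.0,
}


@dataclass
class SimConfig:
    seed: int = 0
    ancestor_len: int = 450
    n_subfamilies: int = 8
    copies_per_subfamily: Union[int, Sequence[int]] = 30
    backbone_branch_subs: float = 0.05
    terminal_branch_subs: Union[float, Sequence[float]] = 0.01
    indel_rate: float = 0.001
    backbone: str = "yule"  # or "ladder" (deterministic caterpillar)
    n_blocks: int = 7
    recomb_events: list = field(default_factory=list)  # (donor, acceptor, block)
    dup_event: Optional[tuple] = None  # (subfam, block)
    motif_gain: Optional[tuple] = None  # (subfam, motif_string, position)
    mark_probs: dict = field(default_factory=dict)  # mark -> prob | {subfam: p}
    activity_windows: dict = field(default_factory=dict)  # subfam -> (start, end)
    species_splits: dict = field(default_factory=lambda: dict(DEFAULT_SPECIES_SPLITS))

    def subfamily_names(self) -> list[str]:
        return [f"sf{i + 1}" for i in range(self.n_subfamilies)]

    def copies(self) -> list[int]:
        if isinstance(self.copies_per_subfamily, int):
            return [self.copies_per_subfamily] * self.n_subfamilies
        return list(self.copies_per_subfamily)

    def terminal_means(self) -> list[float]:
        if isinstance(self.terminal_branch_subs, (int, float)):
            return [float(self.terminal_branch_subs)] * self.n_subfamilies
        return [float(x) for x in self.terminal_branch_subs]

    def windows(self) -> dict:
        if self.activity_windows:
            return dict(self.activity_windows)
        names = self.subfamily_names()
        # split subfamilies into three contiguous waves, oldest first
        out = {}
        k = self.n_subfamilies
        cut1, cut2 = (k + 2) // 3, (2 * k + 1) // 3
        for i, name in enumerate(names):
            wave = 0 if i < cut1 else (1 if i < cut2 else 2)
            out[name] = _DEFAULT_WINDOWS[wave]
        return out

    def validate(self):
        if self.n_subfamilies < 1 or self.ancestor_len < 1:
            raise ValueError("need >=1 subfamily and positive ancestor length")
        if any(c < 1 for c in self.copies()):
            raise ValueError("copies must be >= 1")
        for donor, acceptor, block in self.recomb_events:
            if not 0 <= block < self.n_blocks:
                raise ValueError(f"recombination block index {block} out of range")
        if self.dup_event and not 0 <= self.dup_event[1] < self.n_blocks:
            raise ValueError(f"duplication block index {self.dup_event[1]} out of range")
        for start, end in self.windows().values():
            if not start > end:
                raise ValueError("activity window must have start > end (mya)")
        if self.backbone not in ("yule", "ladder"):
            raise ValueError(f"unknown backbone shape {self.backbone!r}")
        if len(self.terminal_means()) != self.n_subfamilies:
            raise ValueError("terminal_branch_subs list length != n_subfamilies")


@dataclass
class TruthSet:
    config: SimConfig
    elements: list  # seqio.Element
    labels: dict  # element id -> subfamily
    founders: dict  # subfamily -> ungapped founder sequence
    founder_rows: dict  # subfamily -> aligned founder row (family MSA frame)
    alignment: Alignment  # true family MSA (elements only)
    blocks: list  # BlockDefinition in the MSA frame
    events: list  # dicts: {type, ...}
    ages_mya: dict
    terminal_subs: dict  # element -> true terminal branch length (subs/site)
    presence: pd.DataFrame  # elements x species, 0/1
    marks: pd.DataFrame  # elements x marks, 0/1


def mutate_sequence(
    seq: str, branch_subs: float, indel_rate: float, rng: np.random.Generator
) -> str:
    """Jukes-Cantor-style event process on a plain sequence.

    Substitution events are Poisson(branch_subs * L) with uniform sites and
    a uniform choice among the three alternative bases, so multiple hits
    occur and the expected *observed* divergence is
    p = (3/4)(1 - exp(-4 mu / 3)).  Indel events are
    Poisson(indel_rate * L), insertion/deletion equiprobable, geometric
    lengths with mean 3.
    """
    if branch_subs < 0 or indel_rate < 0:
        raise ValueError("rates must be non-negative")
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    arr = _substitute(arr, branch_subs, rng)
    L = len(arr)
    n_indel = rng.poisson(indel_rate * L)
    out = arr
    for _ in range(n_indel):
        pos = int(rng.integers(0, len(out) + 1))
        length = int(rng.geometric(1.0 / 3.0))
        if rng.random() < 0.5 and len(out) > length:  # deletion
            out = np.concatenate([out[:pos], out[pos + length:]])
        else:  # insertion
            ins = _BASES[rng.integers(0, 4, size=length)]
            out = np.concatenate([out[:pos], ins, out[pos:]])
    return out.tobytes().decode()


def _substitute(arr: np.ndarray, branch_subs: float, rng) -> np.ndarray:
    """Apply Poisson(mu*L) substitution events in place on ASCII array."""
    arr = arr.copy()
    live = np.flatnonzero(arr != _GAP)
    n_events = rng.poisson(branch_subs * live.size)
    if n_events:
        sites = live[rng.integers(0, live.size, size=n_events)]
        for s, shift in zip(sites, rng.integers(1, 4, size=n_events)):
            idx = int(np.where(_BASES == arr[s])[0][0]) if arr[s] in _BASES else 0
            arr[s] = _BASES[(idx + shift) % 4]
    return arr


class _Seq:
    """Sequence in the ancestor coordinate frame plus tracked insertions."""

    __slots__ = ("backbone", "insertions")

    def __init__(self, backbone: np.ndarray, insertions: dict | None = None):
        self.backbone = backbone
        self.insertions = dict(insertions or {})  # pos -> uint8 array

    def copy(self) -> "_Seq":
        return _Seq(self.backbone.copy(), {p: v.copy() for p, v in self.insertions.items()})


def _terminal_mutate(seq: _Seq, t: float, indel_rate: float, rng) -> _Seq:
    out = seq.copy()
    out.backbone = _substitute(out.backbone, t, rng)
    L = out.backbone.size
    n_indel = rng.poisson(indel_rate * L)
    for _ in range(n_indel):
        length = int(rng.geometric(1.0 / 3.0))
        if rng.random() < 0.5:  # deletion of backbone positions
            pos = int(rng.integers(0, L))
            out.backbone[pos : pos + length] = _GAP
        else:
            pos = int(rng.integers(0, L + 1))
            ins = _BASES[rng.integers(0, 4, size=length)]
            prev = out.insertions.get(pos)
            out.insertions[pos] = ins if prev is None else np.concatenate([prev, ins])
    return out


def demo_config(seed: int = 0) -> SimConfig:
    """Full-featured study scenario: eight bursting subfamilies in three
    activity waves, one inter-lineage block recombination, one tandem
    block duplication, and an 8-bp motif gained by the youngest lineage."""
    return SimConfig(
        seed=seed,
        recomb_events=[("sf2", "sf7", 3)],
        dup_event=("sf8", 2),
        motif_gain=("sf8", "AAAAGAAG", 160),
    )


def simulate_family(config: SimConfig) -> TruthSet:
    """Generate a family with known subfamily structure; reproducible."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.ancestor_len
    names = config.subfamily_names()
    ancestor = _BASES[rng.integers(0, 4, size=L)]

    # --- founders along the backbone tree ---
    def _branch(parent: _Seq) -> _Seq:
        child = parent.copy()
        child.backbone = _substitute(child.backbone, config.backbone_branch_subs, rng)
        return child

    if config.backbone == "ladder":
        # caterpillar (f1,(f2,(f3, ...))): each founder branches off a spine
        spine = _Seq(ancestor)
        lineages = []
        for _ in range(config.n_subfamilies - 1):
            lineages.append(_branch(spine))
            spine = _branch(spine)
        lineages.append(spine)
    else:  # yule: split a uniformly chosen live lineage
        lineages = [_Seq(ancestor)]
        while len(lineages) < config.n_subfamilies:
            parent = lineages.pop(int(rng.integers(0, len(lineages))))
            lineages.extend([_branch(parent), _branch(parent)])
    founders = {name: lineages[i] for i, name in enumerate(names)}

    bounds = np.linspace(0, L, config.n_blocks + 1).astype(int)
    events = []

    # --- founder-level events (pre-burst) ---
    for donor, acceptor, block in config.recomb_events:
        s, e = bounds[block], bounds[block + 1]
        founders[acceptor].backbone[s:e] = founders[donor].backbone[s:e]
        events.append(
            {"type": "recombination", "donor": donor, "acceptor": acceptor,
             "block": int(block), "start": int(s), "end": int(e)}
        )
    if config.dup_event:
        subfam, block = config.dup_event
        s, e = bounds[block], bounds[block + 1]
        fd = founders[subfam]
        content = fd.backbone[s:e].copy()
        prev = fd.insertions.get(e)
        fd.insertions[e] = content if prev is None else np.concatenate([content, prev])
        events.append({"type": "duplication", "subfamily": subfam,
                       "block": int(block), "start": int(s), "end": int(e)})
    if config.motif_gain:
        subfam, motif, pos = config.motif_gain
        arr = np.frombuffer(motif.encode(), dtype=np.uint8)
        fd = founders[subfam]
        prev = fd.insertions.get(pos)
        fd.insertions[pos] = arr if prev is None else np.concatenate([prev, arr])
        events.append({"type": "motif_gain", "subfamily": subfam,
                       "motif": motif, "position": int(pos)})

    # --- bursts ---
    seqs: dict[str, _Seq] = {}
    labels: dict[str, str] = {}
    terminal_subs: dict[str, float] = {}
    eid = 0
    for name, n_copies, t_mean in zip(names, config.copies(), config.terminal_means()):
        for _ in range(n_copies):
            eid += 1
            elem_id = f"e{eid:04d}"
            t = float(rng.exponential(t_mean))
            seqs[elem_id] = _terminal_mutate(founders[name], t, config.indel_rate, rng)
            labels[elem_id] = name
            terminal_subs[elem_id] = t

    # --- build the exact MSA ---
    all_rows = dict(seqs)
    founder_keys = {f"__founder__{n}": fd for n, fd in founders.items()}
    all_rows.update(founder_keys)
    ins_len = np.zeros(L + 1, dtype=int)
    for sq in all_rows.values():
        for p, v in sq.insertions.items():
            ins_len[p] = max(ins_len[p], v.size)
    total = int(L + ins_len.sum())
    # msa position of backbone column p
    pos_of_col = np.arange(L) + np.cumsum(ins_len)[:L]
    order = list(seqs)
    mat = np.full((len(all_rows), total), _GAP, dtype=np.uint8)
    keys = order + list(founder_keys)
    for r, key in enumerate(keys):
        sq = all_rows[key]
        mat[r, pos_of_col] = sq.backbone
        for p, v in sq.insertions.items():
            start = (pos_of_col[p] if p < L else total) - ins_len[p]
            mat[r, start : start + v.size] = v
    aln = Alignment.from_array(keys, mat)
    founder_rows = {n: aln.rows[len(order) + i] for i, n in enumerate(names)}
    aln = Alignment(order, aln.rows[: len(order)])

    # block definitions mapped into the MSA frame
    blocks = []
    msa_bound = [0]
    for b in bounds[1:-1]:
        msa_bound.append(int(pos_of_col[b]))
    msa_bound.append(total)
    for k in range(config.n_blocks):
        blocks.append(BlockDefinition(f"b{k}", msa_bound[k], msa_bound[k + 1]))

    # --- ages, presence, marks ---
    windows = config.windows()
    ages = {}
    for elem_id, name in labels.items():
        start, end = windows[name]
        ages[elem_id] = float(rng.uniform(end, start))
    species = sorted(config.species_splits, key=config.species_splits.get)
    presence = pd.DataFrame(
        {sp: [int(ages[e] > config.species_splits[sp]) for e in order] for sp in species},
        index=order,
    )
    mark_cols = {}
    for mark, probs in config.mark_probs.items():
        if isinstance(probs, dict):
            p = np.array([probs.get(labels[e], 0.0) for e in order])
        else:
            p = np.full(len(order), float(probs))
        mark_cols[mark] = (rng.random(len(order)) < p).astype(int)
    marks = pd.DataFrame(mark_cols, index=order)

    # --- elements with genomic intervals on a synthetic chromosome ---
    elements = []
    cursor = 100
    for row_i, elem_id in enumerate(order):
        seq = aln.rows[row_i].replace("-", "")
        iv = seqio.GenomicInterval("chrSim", cursor, cursor + len(seq), "+")
        elements.append(seqio.Element(elem_id, iv, seqio.SOLO_LTR, seq))
        cursor += len(seq) + 100

    founder_strs = {n: founder_rows[n].replace("-", "") for n in names}
    return TruthSet(
        config=config, elements=elements, labels=labels, founders=founder_strs,
        founder_rows=founder_rows, alignment=aln, blocks=blocks, events=events,
        ages_mya=ages, terminal_subs=terminal_subs, presence=presence, marks=marks,
    )


def write_truth(truth: TruthSet, outdir) -> None:
    """Write FASTA/BED/TSV artifacts consumed by the rest of the pipeline."""
    os.makedirs(outdir, exist_ok=True)
    j = os.path.join
    seqio.write_fasta(((e.id, e.sequence) for e in truth.elements), j(outdir, "elements.fasta"))
    truth.alignment.to_fasta(j(outdir, "alignment.fasta"))
    seqio.write_fasta(truth.founders.items(), j(outdir, "founders.fasta"))
    with open(j(outdir, "elements.bed"), "w") as fh:
        for e in truth.elements:
            fh.write(f"{e.interval.chrom}\t{e.interval.start}\t{e.interval.end}"
                     f"\t{e.id}\t0\t{e.interval.strand}\n")
    markdir = j(outdir, "marks")
    os.makedirs(markdir, exist_ok=True)
    by_id = {e.id: e for e in truth.elements}
    for mark in truth.marks.columns:
        with open(j(markdir, f"{mark}.bed"), "w") as fh:
            for eid, call in truth.marks[mark].items():
                if call:
                    iv = by_id[eid].interval
                    fh.write(f"{iv.chrom}\t{max(0, iv.start - 10)}\t{iv.end + 10}"
                             f"\t{mark}\t0\t+\n")
    with open(j(outdir, "labels.tsv"), "w") as fh:
        fh.write("element_id\tsubfamily\n")
        for eid, name in truth.labels.items():
            fh.write(f"{eid}\t{name}\n")
    with open(j(outdir, "events.tsv"), "w") as fh:
        fh.write("type\tdetails\n")
        for ev in truth.events:
            fh.write(f"{ev['type']}\t{json.dumps(ev)}\n")
    with open(j(outdir, "blocks.tsv"), "w") as fh:
        fh.write("name\tstart\tend\n")
        for b in truth.blocks:
            fh.write(f"{b.name}\t{b.start}\t{b.end}\n")
    truth.presence.to_csv(j(outdir, "presence.tsv"), sep="\t", index_label="element_id")
    with open(j(outdir, "ages.tsv"), "w") as fh:
        fh.write("element_id\tage_mya\n")
        for eid, age in truth.ages_mya.items():
            fh.write(f"{eid}\t{age:.4f}\n")
    manifest = asdict(truth.config)
    with open(j(outdir, "sim_manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
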