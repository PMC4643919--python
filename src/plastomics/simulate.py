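"""Plastome simulator with ground-truth event logs.

Generates a circular quadripartite root genome (LSC + IRb + SSC + IRa with
IRb = revcomp(IRa) exactly), plants gene annotations including one gene
crossing the IRb/SSC junction, then evolves the genome along a rooted tree
under a directional 12-cell substitution spectrum and a slipped-strand
indel process. Homology is tracked per base (every base has a persistent
column identity), so the true multiple alignment is assembled by
bookkeeping — no aligner is ever invoked — and every analysis stage can be
checked against the logged events.

Model choices worth knowing about:

* IR copies co-evolve: a substitution in IRb is mirrored as its complement
  in IRa, emulating plastid IR copy correction; IR copies therefore stay
  exactly reverse-complementary in every descendant.
* Indels are restricted to single-copy noncoding sequence. Plastid indels
  overwhelmingly accumulate in intergenic spacers and this keeps gene
  annotations and the IR exactly transferable to every leaf.
* A configurable fraction of indels is seeded at repeat contexts
  (homopolymers for 1-bp events, adjacent tandem duplications otherwise),
  the slipped-strand mispairing signature; the rest land uniformly.
* Event counts are per-branch mutation events, not pairwise differences;
  at the shallow divergences simulated here multiple hits are allowed but
  negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .alignment import AlignmentMatrix
from .io import GenomeFeature, PlastomeRecord
from .quadripartite import QuadripartiteStructure
from .spectrum import classify_context

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_root_plastome",
    "evolve_along_tree",
    "simulate",
    "export_fixture",
    "replay_leaf",
    "single_ir_columns",
    "DEFAULT_TREE",
    "DEFAULT_SPECTRUM",
]

# Tilia-like quartet over a cotton-like outgroup: ingroup pairwise
# p-distances land in the low-1e-3 regime, the outgroup ~2e-2 away.
DEFAULT_TREE = (
    "(((TiliaA:0.0005,TiliaB:0.0004):0.0003,"
    "(TiliaC:0.0004,TiliaD:0.0005):0.0002):0.0100,Outgroup:0.0100);"
)

# Directed substitution weights, normalized per ancestral base at use.
# Each row gives its transition 1/3 of the mass, so the event-level Ts/Tv
# ratio is 0.5 whatever the base composition; among transversions A>C (and
# its strand mirror T>G) are in excess while C>G/G>C are depleted.
DEFAULT_SPECTRUM: dict[str, float] = {
    "A>G": 1 / 3, "A>C": 1 / 2, "A>T": 1 / 6,
    "T>C": 1 / 3, "T>G": 1 / 2, "T>A": 1 / 6,
    "C>T": 1 / 3, "C>A": 7 / 12, "C>G": 1 / 12,
    "G>A": 1 / 3, "G>T": 7 / 12, "G>C": 1 / 12,
}

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    """All knobs of the generator; identical (seed, config) ⇒ identical output.

    Region lengths default to the magnitudes of real Malvaceae plastomes
    (~91 kb LSC, ~20 kb SSC, ~25.6 kb IR, GC ≈ 0.365). The indel process
    defaults encode the empirical regime this simulator emulates: indel
    events at ~0.28 per substitution, insertions 41/58 of events, geometric
    lengths with half the mass at 1 bp, and 52/58 of events seeded at a
    repeat context.
    """

    seed: int = 0
    lsc_length: int = 91_000
    ssc_length: int = 20_400
    ir_length: int = 25_600
    gc_content: float = 0.365
    gene_density: float = 0.0005  # genes per single-copy base
    mean_gene_length: int = 900
    intron_probability: float = 0.15
    n_ir_genes: int = 6
    junction_overlap: int = 36  # bases of the JSB-crossing gene inside IRb
    n_repeat_loci: int = 300  # tandem-repeat loci seeded into the root
    tree: str = DEFAULT_TREE
    spectrum: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SPECTRUM))
    indel_substitution_ratio: float = 58 / 208
    insertion_fraction: float = 41 / 58
    indel_length_p: float = 0.5  # geometric success prob; P(len=1)=0.5
    max_indel_length: int = 80
    slip_fraction: float = 52 / 58
    homopolymer_min_run: int = 4

    def validate(self) -> None:
        if not 0 <= self.insertion_fraction <= 1:
            raise ValueError("insertion_fraction must be in [0,1]")
        if not 0 <= self.slip_fraction <= 1:
            raise ValueError("slip_fraction must be in [0,1]")
        if min(self.lsc_length, self.ssc_length, self.ir_length) <= 0:
            raise ValueError("region lengths must be positive")
        if any(w < 0 for w in self.spectrum.values()):
            raise ValueError("spectrum weights must be non-negative")


# ---------------------------------------------------------------------------
# root genome


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _place_intervals(
    rng: np.random.Generator,
    region: tuple[int, int],
    n: int,
    length_sampler,
    occupied: list[tuple[int, int]],
    margin: int = 30,
    edge: int = 60,
    tries_per_gene: int = 200,
) -> list[tuple[int, int]]:
    placed = []
    lo, hi = region
    for _ in range(n):
        for _try in range(tries_per_gene):
            glen = length_sampler()
            if hi - lo - 2 * edge <= glen:
                break
            s = int(rng.integers(lo + edge, hi - edge - glen))
            iv = (s - margin, s + glen + margin)
            if all(iv[1] <= a or iv[0] >= b for a, b in occupied):
                occupied.append((s, s + glen))
                placed.append((s, s + glen))
                break
    return placed


def simulate_root_plastome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[PlastomeRecord, QuadripartiteStructure]:
    """Build the annotated root genome and its true quadripartite structure.

    Layout: LSC [0,l), IRb [l,l+i), SSC [l+i,l+i+s), IRa = revcomp(IRb) at
    the end. One gene ("ycf1") is planted across the IRb/SSC junction with
    ``junction_overlap`` bases inside the IR; tandem-repeat loci are
    scattered through single-copy intergenic sequence to give the
    slipped-strand indel process realistic substrates. The boundary bases
    flanking the IR are adjusted so the planted repeat is maximal — the
    detected IR equals the planted one exactly.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    l, s, i = config.lsc_length, config.ssc_length, config.ir_length
    L = l + s + 2 * i

    lsc = _random_seq(rng, l, config.gc_content)
    irb = _random_seq(rng, i, config.gc_content)
    ssc = _random_seq(rng, s, config.gc_content)
    seq = np.empty(L, dtype=np.uint8)
    seq[0:l] = lsc
    seq[l : l + i] = irb
    seq[l + i : l + i + s] = ssc
    # IRa = revcomp(IRb)
    comp = np.zeros(256, dtype=np.uint8)
    for a, b in zip(b"ACGT", b"TGCA"):
        comp[a] = b
    seq[l + i + s :] = comp[irb][::-1]

    # forbid 1-bp extension of the repeat at either end so the planted IR
    # is the maximal exact match: S[l-1] != comp(S[0]) and
    # S[l+i] != comp(S[l+i+s-1])
    while seq[l - 1] == comp[seq[0]]:
        seq[l - 1] = _random_seq(rng, 1, config.gc_content)[0]
    while seq[l + i] == comp[seq[l + i + s - 1]]:
        seq[l + i] = _random_seq(rng, 1, config.gc_content)[0]

    jsb = l + i  # IRb/SSC boundary
    occupied: list[tuple[int, int]] = []

    # the junction-spanning gene: starts inside IRb, runs into the SSC
    jg_len = max(1500, config.junction_overlap + 600)
    jg = (jsb - config.junction_overlap, jsb - config.junction_overlap + jg_len)
    if config.junction_overlap >= i or jg[1] >= l + i + s - 60:
        raise ValueError("junction_overlap incompatible with region lengths")
    occupied.append(jg)
    features = [
        GenomeFeature("ycf1", "protein_coding", -1, ((jg[0], jg[1]),))
    ]

    def gene_len():
        return max(150, int(rng.normal(config.mean_gene_length, 200)))

    def trna_len():
        return int(rng.integers(70, 90))

    n_sc_genes = max(2, int(round(config.gene_density * (l + s))))
    n_trna = max(1, n_sc_genes // 4)
    n_protein = n_sc_genes - n_trna
    # split proportionally between LSC and SSC
    n_lsc = int(round(n_protein * l / (l + s)))
    gene_ivs = _place_intervals(rng, (0, l), n_lsc, gene_len, occupied)
    gene_ivs += _place_intervals(rng, (jsb, jsb + s), n_protein - n_lsc, gene_len, occupied)
    trna_ivs = _place_intervals(rng, (0, l), n_trna, trna_len, occupied)

    gi = 0
    for s0, e0 in sorted(gene_ivs):
        gi += 1
        strand = 1 if rng.random() < 0.5 else -1
        if rng.random() < config.intron_probability and e0 - s0 >= 450:
            third = (e0 - s0) // 3
            exons = ((s0, s0 + third), (e0 - third, e0))
        else:
            exons = ((s0, e0),)
        features.append(GenomeFeature(f"gene{gi:03d}", "protein_coding", strand, exons))
    for ti, (s0, e0) in enumerate(sorted(trna_ivs), 1):
        strand = 1 if rng.random() < 0.5 else -1
        features.append(GenomeFeature(f"trn{ti:02d}", "tRNA", strand, ((s0, e0),)))

    # IR-resident genes, mirrored into IRa as flagged duplicates
    ir_ivs = _place_intervals(
        rng, (l + 200, jsb - config.junction_overlap - 200),
        config.n_ir_genes, gene_len, occupied,
    )
    for k, (s0, e0) in enumerate(sorted(ir_ivs), 1):
        kind = "rRNA" if k <= min(4, config.n_ir_genes) else "protein_coding"
        name = f"rrn{k}" if kind == "rRNA" else f"irg{k}"
        strand = 1 if rng.random() < 0.5 else -1
        features.append(GenomeFeature(name, kind, strand, ((s0, e0),)))
        # the IRa mirror of IRb offset o sits at L-1-o (reverse complement)
        ms = (l + i + s) + (i - (e0 - l))
        me = (l + i + s) + (i - (s0 - l))
        features.append(
            GenomeFeature(name, kind, -strand, ((ms, me),), is_duplicate=True)
        )

    # tandem-repeat loci in single-copy intergenic sequence
    n_rep = config.n_repeat_loci
    placed = 0
    guard = 0
    gene_blocks = sorted(occupied)
    while placed < n_rep and guard < n_rep * 50:
        guard += 1
        in_lsc = rng.random() < l / (l + s)
        lo, hi = (40, l - 40) if in_lsc else (jsb + 40, jsb + s - 40)
        motif_len = int(rng.integers(1, 7))
        copies = int(rng.integers(2, 5)) if motif_len > 1 else int(rng.integers(4, 9))
        span = motif_len * copies
        p = int(rng.integers(lo, hi - span))
        if any(p < b and p + span > a for a, b in gene_blocks):
            continue
        motif = _random_seq(rng, motif_len, config.gc_content)
        seq[p : p + span] = np.tile(motif, copies)
        placed += 1

    record = PlastomeRecord(
        "root", seq.tobytes().decode(), True, sorted(features, key=lambda f: f.start)
    )
    structure = QuadripartiteStructure(
        L,
        lsc=(0, l),
        irb=(l, l + i),
        ssc=(l + i, l + i + s),
        ira=(l + i + s, 0),
    )
    return record, structure


# ---------------------------------------------------------------------------
# evolution with homology bookkeeping


@dataclass
class SubstitutionTruth:
    branch: str
    site_id: int
    ancestral: str
    derived: str
    mirrored_id: int | None = None


@dataclass
class IndelTruth:
    branch: str
    polarity: str  # insertion | deletion
    anchor_id: int  # id the event sits immediately after (insertions)
    ids: tuple[int, ...]  # inserted or deleted ids
    seq: str
    context: str  # homopolymer | tandem_repeat | none (as generated)


@dataclass
class SyntheticTruth:
    """Everything needed to check any downstream estimate exactly."""

    config: SimulationConfig
    root: PlastomeRecord
    root_structure: QuadripartiteStructure
    alignment: AlignmentMatrix  # leaves only, in tree leaf order
    column_ids: list[int]  # persistent site id per alignment column
    id_region: dict[int, str]  # site id -> LSC | IRB | SSC | IRA
    substitutions: list[SubstitutionTruth]
    indels: list[IndelTruth]
    leaf_records: dict[str, PlastomeRecord]
    leaf_structures: dict[str, QuadripartiteStructure]
    branch_order: list[tuple[str, str]]  # (parent, child) application order
    root_state: dict[int, str]


def _row_probs(spectrum: dict[str, float]) -> dict[str, tuple[list[str], np.ndarray]]:
    rows = {}
    for b in _BASES:
        targets = [t for t in _BASES if t != b]
        w = np.array([spectrum.get(f"{b}>{t}", 0.0) for t in targets], float)
        if w.sum() <= 0:
            raise ValueError(f"spectrum row for {b} has no positive weight")
        rows[b] = (targets, w / w.sum())
    return rows


def _geometric_length(rng, p: float, cap: int) -> int:
    n = int(rng.geometric(p))
    return min(n, cap)


def _find_homopolymer_starts(seq: np.ndarray, min_run: int) -> np.ndarray:
    """Start indices of maximal homopolymer runs of length ≥ min_run."""
    if seq.size < min_run:
        return np.empty(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(seq) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [seq.size]])
    keep = (ends - starts) >= min_run
    return starts[keep]


def _find_tandem_starts(seq: np.ndarray, k: int) -> np.ndarray:
    """Positions p with seq[p:p+k] == seq[p+k:p+2k]."""
    if seq.size < 2 * k:
        return np.empty(0, dtype=np.int64)
    eq = seq[:-k] == seq[k:]
    if k == 1:
        return np.flatnonzero(eq)
    win = np.convolve(eq.astype(np.int32), np.ones(k, dtype=np.int32), "valid")
    return np.flatnonzero(win == k)


class _Lineage:
    """Per-branch mutable view: ordered ids, bases, and indel eligibility."""

    def __init__(self, ids, bases, allowed):
        self.ids = ids  # int64 array
        self.bases = bases  # uint8 array
        self.allowed = allowed  # bool array

    def splice_in(self, pos: int, new_ids: np.ndarray, new_bases: np.ndarray):
        """Insert after index ``pos``."""
        cut = pos + 1
        self.ids = np.concatenate([self.ids[:cut], new_ids, self.ids[cut:]])
        self.bases = np.concatenate([self.bases[:cut], new_bases, self.bases[cut:]])
        self.allowed = np.concatenate(
            [self.allowed[:cut], np.ones(len(new_ids), bool), self.allowed[cut:]]
        )

    def splice_out(self, start: int, end: int):
        keep = np.ones(len(self.ids), bool)
        keep[start:end] = False
        self.ids = self.ids[keep]
        self.bases = self.bases[keep]
        self.allowed = self.allowed[keep]


def evolve_along_tree(
    root: PlastomeRecord,
    root_structure: QuadripartiteStructure,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SyntheticTruth:
    """Evolve the root along the configured tree, returning leaves + truth.

    Per branch of expected ``b`` substitutions/site: the number of
    substitution events is Poisson(b × eligible sites) with sites drawn
    uniformly (IRa mirrors IRb, so IRa sites are not drawn independently);
    indel events are Poisson(ratio × b × eligible sites), applied after the
    substitutions so the homology bookkeeping is unambiguous.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    tree = dendropy.Tree.get(
        data=config.tree, schema="newick", preserve_underscores=True
    )
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise ValueError("tree must have at least two leaves")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length in tree")

    L = root.length
    lsc_len = root_structure.lsc_length
    ir_len = root_structure.ir_length
    ssc_len = root_structure.ssc_length
    irb_s, ssc_s, ira_s = lsc_len, lsc_len + ir_len, lsc_len + ir_len + ssc_len

    def region_of(pos: int) -> str:
        if pos < irb_s:
            return "LSC"
        if pos < ssc_s:
            return "IRB"
        if pos < ira_s:
            return "SSC"
        return "IRA"

    id_region = {i: region_of(i) for i in range(L)}
    mirror = {irb_s + k: L - 1 - k for k in range(ir_len)}
    mirror.update({v: k for k, v in mirror.items()})

    # indel-eligible root positions: single-copy, outside gene extents
    # (±10 bp) and away from the region junctions
    allowed0 = np.zeros(L, bool)
    allowed0[:irb_s] = True
    allowed0[ssc_s:ira_s] = True
    for f in root.features:
        allowed0[max(0, f.start - 10) : f.end + 10] = False
    for j in (0, irb_s, ssc_s, ira_s, L - 1):
        allowed0[max(0, j - 15) : j + 15] = False

    root_bases = np.frombuffer(root.sequence.encode(), dtype=np.uint8)
    rows = _row_probs(config.spectrum)
    comp = {ord(a): ord(b) for a, b in _COMP.items()}

    next_id = L
    children_chains: dict[int, list[list[int]]] = {}
    substitutions: list[SubstitutionTruth] = []
    indels: list[IndelTruth] = []
    branch_order: list[tuple[str, str]] = []
    leaf_states: dict[str, dict[int, str]] = {}
    root_state = {i: chr(root_bases[i]) for i in range(L)}

    _names: dict[int, str] = {}
    for k, nd in enumerate(tree.preorder_node_iter()):
        _names[id(nd)] = nd.taxon.label if nd.taxon else f"node{k}"

    def node_name(node) -> str:
        return _names[id(node)]

    def evolve_branch(parent_lin: _Lineage, state: dict[int, str], branch: str, bl: float):
        nonlocal next_id
        lin = _Lineage(parent_lin.ids.copy(), parent_lin.bases.copy(), parent_lin.allowed.copy())
        not_ira = np.array([id_region.get(int(i), "LSC") != "IRA" for i in lin.ids])
        eligible_idx = np.flatnonzero(not_ira)
        n_eff = len(eligible_idx)

        # --- substitutions ---
        n_sub = int(rng.poisson(bl * n_eff))
        if n_sub:
            picks = rng.choice(eligible_idx, size=n_sub)
            for p in picks:
                sid = int(lin.ids[p])
                old = chr(lin.bases[p])
                targets, probs = rows[old]
                new = targets[int(rng.choice(4 - 1, p=probs))]
                lin.bases[p] = ord(new)
                state[sid] = new
                mid = mirror.get(sid)
                if mid is not None and mid in state:
                    state[mid] = _COMP[new]
                    # mirrored base lives in IRa, outside lin eligibility,
                    # but is present in lin.ids; update its array cell too
                    mp = np.flatnonzero(lin.ids == mid)
                    if mp.size:
                        lin.bases[mp[0]] = ord(_COMP[new])
                substitutions.append(
                    SubstitutionTruth(branch, sid, old, new, mid)
                )

        # --- indels ---
        n_ind = int(rng.poisson(config.indel_substitution_ratio * bl * n_eff))
        for _ in range(n_ind):
            is_ins = rng.random() < config.insertion_fraction
            length = _geometric_length(rng, config.indel_length_p, config.max_indel_length)
            slip = rng.random() < config.slip_fraction
            _apply_indel(lin, state, branch, is_ins, length, slip, config, rng)
        return lin

    def _apply_indel(lin: _Lineage, state, branch, is_ins, length, slip, cfg, rng):
        nonlocal next_id
        seq = lin.bases
        allowed = lin.allowed
        hp_min = cfg.homopolymer_min_run

        def log_event(polarity, anchor_pos, ids, bases, ctx_override=None):
            left = seq_snapshot[max(0, pos_l - 8) : pos_l].tobytes().decode()
            right = seq_snapshot[pos_r : pos_r + 8].tobytes().decode()
            ctx = ctx_override or classify_context(
                bases.tobytes().decode(), left, right, hp_min
            )
            indels.append(
                IndelTruth(
                    branch,
                    polarity,
                    int(lin.ids[anchor_pos]) if anchor_pos >= 0 else -1,
                    tuple(int(x) for x in ids),
                    bases.tobytes().decode(),
                    ctx,
                )
            )
            return ctx

        if is_ins:
            if slip and length == 1:
                starts = _find_homopolymer_starts(seq, max(2, hp_min - 1))
                starts = starts[allowed[starts]]
                if starts.size == 0:
                    slip = False
                else:
                    p = int(starts[rng.integers(starts.size)])
                    base = seq[p]
                    new_ids = np.array([next_id], dtype=np.int64)
                    new_bases = np.array([base], dtype=np.uint8)
                    seq_snapshot, pos_l, pos_r = seq, p + 1, p + 1
                    log_event("insertion", p, new_ids, new_bases)
                    _register_insert(lin, p, new_ids, new_bases, state)
                    return True
            if slip and length > 1:
                # tandem duplication: copy the motif at p..p+length after itself
                cand = np.flatnonzero(
                    np.convolve(allowed.astype(np.int32), np.ones(length, np.int32), "valid")
                    == length
                )
                if cand.size == 0:
                    slip = False
                else:
                    p = int(cand[rng.integers(cand.size)])
                    motif = seq[p : p + length].copy()
                    new_ids = np.arange(next_id, next_id + length, dtype=np.int64)
                    new_bases = motif
                    seq_snapshot, pos_l, pos_r = seq, p + length, p + length
                    log_event("insertion", p + length - 1, new_ids, new_bases)
                    _register_insert(lin, p + length - 1, new_ids, new_bases, state)
                    return True
            # uniform insertion of random bases
            sites = np.flatnonzero(allowed)
            if sites.size == 0:
                return None
            p = int(sites[rng.integers(sites.size)])
            new_bases = _random_seq(rng, length, cfg.gc_content)
            new_ids = np.arange(next_id, next_id + length, dtype=np.int64)
            seq_snapshot, pos_l, pos_r = seq, p + 1, p + 1
            log_event("insertion", p, new_ids, new_bases)
            _register_insert(lin, p, new_ids, new_bases, state)
            return True
        else:
            if slip and length == 1:
                starts = _find_homopolymer_starts(seq, hp_min)
                starts = starts[allowed[starts]]
                if starts.size:
                    p = int(starts[rng.integers(starts.size)])
                    ids = lin.ids[p : p + 1]
                    bases = seq[p : p + 1].copy()
                    seq_snapshot, pos_l, pos_r = seq.copy(), p, p + 1
                    log_event("deletion", p - 1, ids, bases)
                    _register_delete(lin, p, p + 1, state)
                    return True
                slip = False
            if slip and length > 1:
                cand = _find_tandem_starts(seq, length)
                okc = np.empty(0, np.int64)
                if cand.size and allowed.size >= 2 * length:
                    win = np.convolve(
                        allowed.astype(np.int32), np.ones(2 * length, np.int32), "valid"
                    )
                    okc = cand[cand < win.size]
                    okc = okc[win[okc] == 2 * length]
                if okc.size:
                    p = int(okc[rng.integers(okc.size)]) + length  # delete 2nd copy
                    ids = lin.ids[p : p + length]
                    bases = seq[p : p + length].copy()
                    seq_snapshot, pos_l, pos_r = seq.copy(), p, p + length
                    log_event("deletion", p - 1, ids, bases)
                    _register_delete(lin, p, p + length, state)
                    return True
                slip = False
            # uniform deletion of an allowed run
            if allowed.size < length:
                return None
            runs = np.convolve(allowed.astype(np.int32), np.ones(length, np.int32), "valid")
            sites = np.flatnonzero(runs == length)
            if sites.size == 0:
                return None
            p = int(sites[rng.integers(sites.size)])
            ids = lin.ids[p : p + length]
            bases = seq[p : p + length].copy()
            seq_snapshot, pos_l, pos_r = seq.copy(), p, p + length
            log_event("deletion", p - 1, ids, bases)
            _register_delete(lin, p, p + length, state)
            return True

    def _register_insert(lin: _Lineage, pos, new_ids, new_bases, state):
        nonlocal next_id
        anchor = int(lin.ids[pos])
        children_chains.setdefault(anchor, []).append([int(x) for x in new_ids])
        for sid, b in zip(new_ids, new_bases):
            state[int(sid)] = chr(b)
            id_region[int(sid)] = id_region.get(anchor, "LSC")
        next_id += len(new_ids)
        lin.splice_in(pos, new_ids, new_bases)

    def _register_delete(lin: _Lineage, start, end, state):
        for sid in lin.ids[start:end]:
            del state[int(sid)]
        lin.splice_out(start, end)

    # recursive traversal
    root_lin = _Lineage(
        np.arange(L, dtype=np.int64), root_bases.copy(), allowed0.copy()
    )

    def walk(node, lin: _Lineage, state: dict[int, str]):
        for child in node.child_nodes():
            bl = child.edge.length or 0.0
            cname = node_name(child)
            branch_order.append((node_name(node), cname))
            cstate = dict(state)
            clin = evolve_branch(lin, cstate, cname, bl)
            if child.is_leaf():
                leaf_states[cname] = cstate
            else:
                walk(child, clin, cstate)

    walk(tree.seed_node, root_lin, root_state)

    # ---- final master ordering: root order with insertion chains expanded
    # (an inserted run sits immediately after its anchor id; runs anchored
    # at the same id stack in order of creation; nesting recurses)
    master: list[int] = []

    def expand(idv: int):
        master.append(idv)
        for chain in children_chains.get(idv, ()):
            for cid in chain:
                expand(cid)

    for rid in range(L):
        expand(rid)

    # ---- alignment over columns alive in at least one leaf
    alive_any = set()
    for st in leaf_states.values():
        alive_any.update(st.keys())
    column_ids = [i for i in master if i in alive_any]
    col_index = {cid: k for k, cid in enumerate(column_ids)}
    ncol = len(column_ids)
    mat = np.full((len(leaves), ncol), ord("-"), dtype=np.uint8)
    for r, lf in enumerate(leaves):
        st = leaf_states[lf]
        for sid, b in st.items():
            mat[r, col_index[sid]] = ord(b)
    aln = AlignmentMatrix(leaves, mat)

    # ---- leaf records and structures
    leaf_records: dict[str, PlastomeRecord] = {}
    leaf_structures: dict[str, QuadripartiteStructure] = {}
    for lf in leaves:
        st = leaf_states[lf]
        ordered = [i for i in column_ids if i in st]
        seq = "".join(st[i] for i in ordered)
        pos_of = {sid: k for k, sid in enumerate(ordered)}
        feats = []
        for f in root.features:
            exons = tuple(
                (pos_of[s0], pos_of[e0 - 1] + 1) for s0, e0 in f.exons
            )
            feats.append(GenomeFeature(f.name, f.kind, f.strand, exons, f.is_duplicate))
        leaf_records[lf] = PlastomeRecord(lf, seq, True, feats)
        counts = {"LSC": 0, "IRB": 0, "SSC": 0, "IRA": 0}
        for i in ordered:
            counts[id_region[i]] += 1
        nL, nB, nS = counts["LSC"], counts["IRB"], counts["SSC"]
        leaf_structures[lf] = QuadripartiteStructure(
            len(seq),
            lsc=(0, nL),
            irb=(nL, nL + nB),
            ssc=(nL + nB, nL + nB + nS),
            ira=((nL + nB + nS) % len(seq), 0),
        )

    return SyntheticTruth(
        config=config,
        root=root,
        root_structure=root_structure,
        alignment=aln,
        column_ids=column_ids,
        id_region=id_region,
        substitutions=substitutions,
        indels=indels,
        leaf_records=leaf_records,
        leaf_structures=leaf_structures,
        branch_order=branch_order,
        root_state={i: chr(root_bases[i]) for i in range(L)},
    )


def simulate(config: SimulationConfig) -> SyntheticTruth:
    """Root generation + tree evolution under one seed."""
    rng = np.random.default_rng(config.seed)
    root, structure = simulate_root_plastome(config, rng)
    return evolve_along_tree(root, structure, config, rng)


# ---------------------------------------------------------------------------
# truth utilities


def single_ir_columns(truth: SyntheticTruth) -> np.ndarray:
    """Indices of alignment columns outside the IRa copy (one-IR view)."""
    return np.array(
        [k for k, cid in enumerate(truth.column_ids) if truth.id_region[cid] != "IRA"],
        dtype=np.int64,
    )


def replay_leaf(truth: SyntheticTruth, leaf: str) -> str:
    """Re-apply the logged events from the root state down to ``leaf`` and
    return the reconstructed sequence; must equal the stored leaf exactly."""
    # find the branch path root→leaf from the recorded application order
    parents = {c: p for p, c in truth.branch_order}
    path = [leaf]
    while path[-1] in parents:
        path.append(parents[path[-1]])
    path.reverse()  # root ... leaf
    on_path = set(zip(path, path[1:]))

    state = dict(truth.root_state)
    events: list[tuple[int, object]] = []
    # logged lists are in application order; merge keeping that order
    branch_of = {}
    for i, s in enumerate(truth.substitutions):
        events.append((("S", i), s))
    for i, d in enumerate(truth.indels):
        events.append((("I", i), d))

    # application order must interleave substitutions and indels per branch:
    # within a branch all substitutions precede all indels (by construction)
    branch_seq = [c for _, c in truth.branch_order]
    rank = {b: i for i, b in enumerate(branch_seq)}
    events.sort(key=lambda kv: (rank[kv[1].branch], kv[0][0] == "I", kv[0][1]))

    for _, ev in events:
        pb = parents.get(ev.branch)
        if (pb, ev.branch) not in on_path:
            continue
        if isinstance(ev, SubstitutionTruth):
            state[ev.site_id] = ev.derived
            if ev.mirrored_id is not None and ev.mirrored_id in state:
                state[ev.mirrored_id] = _COMP[ev.derived]
        else:
            if ev.polarity == "insertion":
                for sid, b in zip(ev.ids, ev.seq):
                    state[sid] = b
            else:
                for sid in ev.ids:
                    state.pop(sid, None)
    return "".join(state[i] for i in truth.column_ids if i in state)


# ---------------------------------------------------------------------------
# fixture export


def export_fixture(truth: SyntheticTruth, out_dir) -> dict[str, str]:
    """Write the simulation as files consumable by the analysis CLIs.

    Produces one GenBank per leaf, the true alignment (full and one-IR
    view) as aligned FASTA, a region TSV mapping root noncoding loci to
    alignment columns, truth-log TSVs, and a structure TSV per leaf.
    """
    import os

    from . import io as pio
    from .sizecomp import partition_genome

    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for lf, rec in truth.leaf_records.items():
        p = os.path.join(out_dir, f"{lf}.gb")
        pio.write_genbank(rec, p)
        paths[f"genbank:{lf}"] = p

    aln_path = os.path.join(out_dir, "alignment.fasta")
    pio.write_alignment(truth.alignment, aln_path)
    paths["alignment"] = aln_path

    keep = single_ir_columns(truth)
    sub = AlignmentMatrix(list(truth.alignment.taxa), truth.alignment.matrix[:, keep])
    one_ir_path = os.path.join(out_dir, "alignment.one_ir.fasta")
    pio.write_alignment(sub, one_ir_path)
    paths["alignment_one_ir"] = one_ir_path

    # noncoding loci of the root, mapped to full-alignment columns
    part = partition_genome(truth.root, truth.root_structure)
    col_of = {cid: k for k, cid in enumerate(truth.column_ids)}
    regions_path = os.path.join(out_dir, "regions.tsv")
    with open(regions_path, "w") as fh:
        fh.write("#name\tklass\tcol_start\tcol_end\n")
        for e in part.elements:
            if e.klass not in ("IGS", "intron"):
                continue
            s0, e0 = e.interval
            cols = [col_of[i] for i in range(s0, e0) if i in col_of]
            if not cols:
                continue
            cs = min(cols)
            ce = max(cols) + 1
            fh.write(f"{e.name}\t{e.klass}\t{cs + 1}\t{ce}\n")
    paths["regions"] = regions_path

    subs_path = os.path.join(out_dir, "truth_substitutions.tsv")
    with open(subs_path, "w") as fh:
        fh.write("#branch\tcolumn\tancestral\tderived\n")
        for s in truth.substitutions:
            col = col_of.get(s.site_id)
            fh.write(f"{s.branch}\t{'' if col is None else col + 1}\t{s.ancestral}\t{s.derived}\n")
    paths["truth_substitutions"] = subs_path

    ind_path = os.path.join(out_dir, "truth_indels.tsv")
    with open(ind_path, "w") as fh:
        fh.write("#branch\tpolarity\tlength\tcontext\tseq\tcolumns\n")
        for d in truth.indels:
            cols = sorted(col_of[i] for i in d.ids if i in col_of)
            span = f"{cols[0] + 1}-{cols[-1] + 1}" if cols else ""
            fh.write(
                f"{d.branch}\t{d.polarity}\t{len(d.seq)}\t{d.context}\t{d.seq}\t{span}\n"
            )
    paths["truth_indels"] = ind_path

    struct_path = os.path.join(out_dir, "structures.tsv")
    with open(struct_path, "w") as fh:
        fh.write("#leaf\tlsc\tssc\tir\tlength\n")
        for lf, st in truth.leaf_structures.items():
            fh.write(
                f"{lf}\t{st.lsc_length}\t{st.ssc_length}\t{st.ir_length}\t{st.genome_length}\n"
            )
    paths["structures"] = struct_path
    return paths
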