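"""Synthetic data generation with planted ground truth.

Everything the survey pipeline consumes can be simulated here: diploid
ZW/ZZ genomes with known GC, heterozygosity, repeat content, microsatellite
loci and female-specific (W) segments; Illumina-like paired-end read sets;
and sets of annotated circular mitogenomes diverged along a known tree.

Design notes
------------
* Background sequence uses exact base composition (a permutation of a fixed
  multiset of bases at the target GC) rather than i.i.d. draws, so the
  realized GC of every emitted genome matches its target to within rounding.
* Heterozygosity is applied as substitutions only, outside planted SSR loci,
  so that microsatellite truth stays intact on both haplotypes.
* W-specific segments are drawn from a fresh random stream and screened so
  that no exact 31-mer is shared with the rest of the genome; the subtractive
  marker pipeline therefore has a recoverable ground truth.
* The W-bearing haplotype may additionally *lose* sequence (``z_loss_bases``),
  emulating W-chromosome degeneration; this is what makes a ZW female's
  k-mer genome-size estimate smaller than the ZZ male's, as observed in
  heterogametic taxa.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import _seq
from .tree import PhyloTree, TreeNode, random_tree

DEFAULT_SSR_THRESHOLDS = (12, 7, 5, 5, 5, 5)  # min repeats for unit sizes 1..6
_W_SCREEN_K = 31


class ParameterError(ValueError):
    """A simulation parameter failed validation; the message names the field."""


@dataclass
class SimulationParams:
    """Knobs of the diploid genome / read simulator.

    Defaults mirror a desk-scale version of a cyprinid genome survey:
    GC 36.95%, heterozygosity 0.39%, one third repeats, 2x150 bp pairs with
    350 bp inserts at 60x coverage.
    """

    genome_length: int = 1_000_000
    gc_target: float = 0.3695
    heterozygosity: float = 0.0039
    repeat_fraction: float = 0.33
    repeat_unit_lengths: tuple[int, ...] = (300, 700, 1500)
    ssr_density: float = 50.0            # planted SSR loci per Mb
    sex_system: str = "ZW_female"        # or "ZZ_male"
    w_segment_count: int = 10
    w_segment_lengths: tuple[int, ...] = (1500,)
    z_loss_bases: int = 0                # bases deleted from the W haplotype
    read_length: int = 150
    insert_size: int = 350
    insert_sigma: float = 30.0
    coverage: float = 60.0
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sex_system not in ("ZW_female", "ZZ_male"):
            raise ParameterError("sex_system must be ZW_female or ZZ_male")
        if self.sex_system == "ZZ_male":
            self.w_segment_count = 0
        if not 0 <= self.gc_target <= 1:
            raise ParameterError("gc_target must lie in [0, 1]")
        if not 0 <= self.heterozygosity <= 0.05:
            raise ParameterError("heterozygosity must lie in [0, 0.05]")
        if not 0 <= self.repeat_fraction <= 0.9:
            raise ParameterError("repeat_fraction must lie in [0, 0.9]")
        if self.genome_length <= 0:
            raise ParameterError("genome_length must be positive")
        if self.w_segment_count < 0:
            raise ParameterError("w_segment_count must be >= 0")
        if self.w_segment_count and min(self.w_segment_lengths) < 400:
            raise ParameterError("w_segment_lengths must each be >= 400")
        if not 0 <= self.error_rate < 1:
            raise ParameterError("error_rate must lie in [0, 1)")
        if self.read_length > self.insert_size:
            raise ParameterError("read_length must not exceed insert_size")


@dataclass
class Feature:
    """An annotated interval, 0-based half-open, on one haplotype sequence."""

    kind: str                  # 'repeat' | 'ssr' | 'w_segment'
    haplotype: str
    start: int
    end: int
    attrs: dict = field(default_factory=dict)


class DiploidGenome:
    """Two haplotype sequences plus planted-feature annotations."""

    def __init__(self, seqs: dict[str, np.ndarray], features: list[Feature],
                 truth: dict):
        self.seqs = seqs
        self.features = features
        self.truth = truth
        for f in features:
            if not (0 <= f.start < f.end <= len(self.seqs[f.haplotype])):
                raise ValueError(f"feature interval out of bounds: {f}")

    @property
    def haplotype_names(self) -> list[str]:
        return list(self.seqs)

    def sequence(self, name: str) -> str:
        return _seq.decode(self.seqs[name])

    def haploid_length(self) -> float:
        return sum(len(s) for s in self.seqs.values()) / len(self.seqs)

    def gc_content(self) -> float:
        total = sum(len(s) for s in self.seqs.values())
        gc = sum(int(((s == 1) | (s == 2)).sum()) for s in self.seqs.values())
        return gc / total

    def features_of(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def realized_mismatch_rate(self) -> float:
        """Direct per-site mismatch rate between haplotypes, after removing
        W-specific insertions and degeneration deletions from the comparison
        (both are tracked in the truth block)."""
        h1, h2 = (self.seqs[n] for n in self.haplotype_names)
        cut = sorted(self.truth.get("hap2_indels", []))
        if cut:
            keep = np.ones(len(h2), dtype=bool)
            rebuilt = []
            pos2 = 0
            # hap2_indels stores (pos_in_hap2, delta): delta>0 insertion of
            # that many bases at pos; delta<0 deletion site (bases missing
            # from hap2). Reconstruct comparable arrays.
            a_parts, b_parts = [], []
            pos1 = 0
            for pos, delta in cut:
                if delta > 0:      # insertion into hap2: skip those bases
                    b_parts.append(h2[pos2:pos])
                    a_parts.append(h1[pos1:pos1 + (pos - pos2)])
                    pos1 += pos - pos2
                    pos2 = pos + delta
                else:              # deletion from hap2: skip hap1 bases
                    b_parts.append(h2[pos2:pos])
                    a_parts.append(h1[pos1:pos1 + (pos - pos2)])
                    pos1 += (pos - pos2) - delta
                    pos2 = pos
            b_parts.append(h2[pos2:])
            a_parts.append(h1[pos1:pos1 + (len(h2) - pos2)])
            h1 = np.concatenate(a_parts)
            h2 = np.concatenate(b_parts)
        n = min(len(h1), len(h2))
        return float((h1[:n] != h2[:n]).sum() / n)

    # -- output ------------------------------------------------------------

    def write_fasta(self, path) -> None:
        from .io import write_fasta
        write_fasta(path, [(n, self.sequence(n)) for n in self.haplotype_names])

    def write_gff3(self, path) -> None:
        from .io import write_gff3
        rows = [(f.haplotype, "genomesurvey", f.kind, f.start + 1, f.end, ".",
                 "+", ".", ";".join(f"{k}={v}" for k, v in f.attrs.items()) or ".")
                for f in self.features]
        write_gff3(path, rows)

    def write_truth_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# genome construction helpers


def _exact_composition(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    """Permutation of a fixed base multiset hitting ``gc`` to within rounding."""
    n_gc = int(round(gc * length))
    g = n_gc // 2
    c = n_gc - g
    a = (length - n_gc) // 2
    t = length - n_gc - a
    arr = np.concatenate([
        np.zeros(a, np.uint8), np.full(c, 1, np.uint8),
        np.full(g, 2, np.uint8), np.full(t, 3, np.uint8)])
    return rng.permutation(arr)


def _nonperiodic_motif(u: int, rng: np.random.Generator) -> np.ndarray:
    while True:
        m = rng.integers(0, 4, u).astype(np.uint8)
        if u == 1:
            return m
        ok = True
        for p in range(1, u):
            if u % p == 0 and np.array_equal(m, np.tile(m[:p], u // p)):
                ok = False
                break
        if ok:
            return m


def _pick_free_position(length_needed: int, genome_len: int,
                        blocked: list[tuple[int, int]],
                        rng: np.random.Generator,
                        guard: int = 150, tries: int = 300) -> int | None:
    for _ in range(tries):
        p = int(rng.integers(guard, genome_len - length_needed - guard))
        lo, hi = p - guard, p + length_needed + guard
        if all(e <= lo or s >= hi for s, e in blocked):
            return p
    return None


def _plan_repeats(params: SimulationParams, rng: np.random.Generator):
    """Choose repeat families (unit length, copy number) totalling about
    repeat_fraction x genome_length bases."""
    target = params.repeat_fraction * params.genome_length
    fams = []
    total = 0
    i = 0
    while total < target:
        unit_len = int(params.repeat_unit_lengths[i % len(params.repeat_unit_lengths)])
        copies = int(rng.integers(2, 9))
        if total + unit_len * copies > target * 1.02 + unit_len:
            copies = max(2, int((target - total) // unit_len))
            if copies < 2 or total + unit_len * copies > target * 1.1:
                break
        fams.append((f"repfam{i}", unit_len, copies))
        total += unit_len * copies
        i += 1
    return fams, total


def simulate_diploid_genome(params: SimulationParams) -> DiploidGenome:
    """Build a two-haplotype genome with planted repeats, SSRs, heterozygous
    substitutions and (for ZW females) W-specific segments.

    Deterministic for a fixed ``params.seed``.
    """
    rng = np.random.default_rng([params.seed, 0])
    L = params.genome_length

    fams, repeat_total = _plan_repeats(params, rng)
    unique_len = L - repeat_total
    if unique_len <= 0:
        raise ParameterError("repeat_fraction leaves no unique sequence")

    unique = _exact_composition(unique_len, params.gc_target, rng)
    units = {name: _exact_composition(ul, params.gc_target, rng)
             for name, ul, _ in fams}

    # interleave repeat copies into the unique background at random cuts
    copies = [(name, units[name]) for name, _, cn in fams for _ in range(cn)]
    order = rng.permutation(len(copies))
    cuts = np.sort(rng.integers(0, unique_len + 1, len(copies)))
    parts, feats = [], []
    pos_out = 0
    prev = 0
    for ci, cut in zip(order, cuts):
        name, unit = copies[ci]
        parts.append(unique[prev:cut])
        pos_out += cut - prev
        parts.append(unit)
        feats.append(Feature("repeat", "hap1", pos_out, pos_out + len(unit),
                             {"family": name}))
        pos_out += len(unit)
        prev = cut
    parts.append(unique[prev:])
    hap1 = np.concatenate(parts) if parts else unique
    assert len(hap1) == L

    blocked = [(f.start, f.end) for f in feats]

    # plant SSR loci in the unique background
    n_ssr = int(round(params.ssr_density * L / 1e6))
    unit_choices = rng.choice(np.arange(1, 7), size=n_ssr,
                              p=[0.4, 0.25, 0.1, 0.1, 0.075, 0.075])
    ssr_mask = np.zeros(L, dtype=bool)
    for u in unit_choices:
        u = int(u)
        reps = int(DEFAULT_SSR_THRESHOLDS[u - 1] + rng.integers(0, 10))
        span = u * reps
        p = _pick_free_position(span, L, blocked, rng)
        if p is None:
            continue
        motif = _nonperiodic_motif(u, rng)
        hap1[p:p + span] = np.tile(motif, reps)
        # enforce maximality: break the period at both flanks
        for flank, partner in ((p - 1, p - 1 + u), (p + span, p + span - u)):
            if hap1[flank] == hap1[partner]:
                choices = [b for b in range(4)
                           if b != hap1[partner] and b != hap1[flank + (1 if flank < p else -1)]]
                hap1[flank] = choices[int(rng.integers(0, len(choices)))]
        feats.append(Feature("ssr", "hap1", p, p + span,
                             {"motif": _seq.decode(motif), "unit": u, "repeats": reps}))
        blocked.append((p, p + span))
        ssr_mask[p:p + span] = True

    # haplotype 2: substitutions outside SSR loci
    hap2 = hap1.copy()
    sub_sites = np.flatnonzero(rng.random(L) < params.heterozygosity)
    sub_sites = sub_sites[~ssr_mask[sub_sites]]
    if sub_sites.size:
        shift = rng.integers(1, 4, sub_sites.size).astype(np.uint8)
        hap2[sub_sites] = (hap2[sub_sites] + shift) % 4
    realized_het = sub_sites.size / L

    hap2_feats = [Feature(f.kind, "hap2", f.start, f.end, dict(f.attrs))
                  for f in feats]

    # edits on hap2: W-segment insertions and degeneration deletions,
    # confined to feature-free zones so annotation remapping is a pure shift
    edits: list[tuple[int, int, np.ndarray | None, int | None]] = []
    w_rng = np.random.default_rng([params.seed, 7])  # distinct W stream
    w_lengths = []
    if params.w_segment_count:
        background = np.concatenate([hap1, hap2])
        bg_codes, bg_valid = _seq.kmer_codes_1d(background, _W_SCREEN_K)
        bg_set = np.unique(_seq.canonical_kmer_codes(bg_codes[bg_valid], _W_SCREEN_K))
        for wi in range(params.w_segment_count):
            wl = int(params.w_segment_lengths[wi % len(params.w_segment_lengths)])
            for _attempt in range(25):
                seg = _exact_composition(wl, params.gc_target, w_rng)
                kc, _ = _seq.kmer_codes_1d(seg, _W_SCREEN_K)
                canon = _seq.canonical_kmer_codes(kc, _W_SCREEN_K)
                idx = np.searchsorted(bg_set, canon)
                idx = np.clip(idx, 0, len(bg_set) - 1)
                if not (bg_set[idx] == canon).any():
                    break
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not generate a clean W segment")
            p = _pick_free_position(1, L, blocked, rng)
            if p is None:
                raise RuntimeError("no free position for W segment")
            blocked.append((p, p + 1))
            edits.append((p, wl, seg, wi))
            w_lengths.append(wl)

    if params.z_loss_bases > 0:
        n_del = max(1, params.z_loss_bases // 2000)
        dlen = params.z_loss_bases // n_del
        for _ in range(n_del):
            p = _pick_free_position(dlen, L, blocked, rng)
            if p is None:
                break
            blocked.append((p, p + dlen))
            edits.append((p, -dlen, None, None))

    # apply edits left-to-right, remapping hap2 features by cumulative offset
    edits.sort(key=lambda e: e[0])
    if edits:
        parts = []
        prev = 0
        offset = 0
        shift_at: list[tuple[int, int]] = []   # (hap1 pos, new cumulative offset)
        indels: list[tuple[int, int]] = []     # (pos in final hap2, delta)
        w_feats: list[Feature] = []
        for p, delta, payload, wi in edits:
            parts.append(hap2[prev:p])
            if delta > 0:
                out_pos = p + offset
                parts.append(payload)
                w_feats.append(Feature("w_segment", "hap2", out_pos,
                                       out_pos + delta, {"w_index": wi}))
                indels.append((out_pos, delta))
                offset += delta
                prev = p
            else:
                indels.append((p + offset, delta))
                offset += delta
                prev = p - delta
            shift_at.append((prev, offset))
        parts.append(hap2[prev:])
        hap2 = np.concatenate(parts)

        def remap(pos: int) -> int:
            off = 0
            for at, o in shift_at:
                if pos >= at:
                    off = o
                else:
                    break
            return pos + off

        for f in hap2_feats:
            f.start, f.end = remap(f.start), remap(f.end)
        hap2_feats.extend(w_feats)
    else:
        indels = []

    features = feats + hap2_feats
    seqs = {"hap1": hap1, "hap2": hap2}

    realized_gc = (int(((hap1 == 1) | (hap1 == 2)).sum())
                   + int(((hap2 == 1) | (hap2 == 2)).sum())) / (len(hap1) + len(hap2))
    if abs(realized_gc - params.gc_target) > 0.005:
        raise RuntimeError(
            f"realized GC {realized_gc:.4f} deviates from target {params.gc_target:.4f}")

    truth = {
        "params": dataclasses.asdict(params),
        "realized_gc": realized_gc,
        "realized_heterozygosity": realized_het,
        "repeat_bases": repeat_total,
        "repeat_fraction_realized": repeat_total / L,
        "ssr_planted": sum(1 for f in feats if f.kind == "ssr"),
        "w_segment_lengths": w_lengths,
        "hap2_indels": indels,
    }
    return DiploidGenome(seqs, features, truth)


# ---------------------------------------------------------------------------
# reads


class ReadSet:
    """Paired-end reads held as numeric matrices, with per-pair provenance.

    Read names encode the origin: ``pair<i>:<hap>:<start>:<insert>:<F|R>/<mate>``.
    """

    QUAL_CHAR = "F"  # constant Q37; read QC is outside this package's scope

    def __init__(self, r1: np.ndarray, r2: np.ndarray, hap_names: list[str],
                 hap_idx: np.ndarray, start: np.ndarray, insert: np.ndarray,
                 flip: np.ndarray):
        self.r1 = r1
        self.r2 = r2
        self.hap_names = hap_names
        self.hap_idx = hap_idx
        self.start = start
        self.insert = insert
        self.flip = flip

    @property
    def n_pairs(self) -> int:
        return self.r1.shape[0]

    @property
    def read_length(self) -> int:
        return self.r1.shape[1]

    def name(self, i: int, mate: int) -> str:
        return (f"pair{i}:{self.hap_names[self.hap_idx[i]]}:{self.start[i]}:"
                f"{self.insert[i]}:{'R' if self.flip[i] else 'F'}/{mate}")

    def sequences(self) -> np.ndarray:
        """All reads (R1 then R2) as one (2N x L) code matrix."""
        return np.vstack([self.r1, self.r2])

    def pairs(self):
        q = self.QUAL_CHAR * self.read_length
        for i in range(self.n_pairs):
            yield ((self.name(i, 1), _seq.decode(self.r1[i]), q),
                   (self.name(i, 2), _seq.decode(self.r2[i]), q))

    def subset(self, mask: np.ndarray) -> "ReadSet":
        return ReadSet(self.r1[mask], self.r2[mask], self.hap_names,
                       self.hap_idx[mask], self.start[mask],
                       self.insert[mask], self.flip[mask])

    def to_fastq(self, r1_path, r2_path) -> None:
        q = self.QUAL_CHAR * self.read_length
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for i in range(self.n_pairs):
                f1.write(f"@{self.name(i, 1)}\n{_seq.decode(self.r1[i])}\n+\n{q}\n")
                f2.write(f"@{self.name(i, 2)}\n{_seq.decode(self.r2[i])}\n+\n{q}\n")


def simulate_reads(genome: DiploidGenome, params: SimulationParams,
                   seed: int | None = None) -> ReadSet:
    """Uniform paired-end sampling from both haplotypes at the configured
    coverage, with independent per-base miscalls at ``error_rate``."""
    if params.coverage <= 0:
        raise ParameterError("coverage must be positive")
    if params.read_length > params.insert_size:
        raise ParameterError("read_length must not exceed insert_size")
    rng = np.random.default_rng([params.seed if seed is None else seed, 1])
    rl = params.read_length
    haps = [genome.seqs[n] for n in genome.haplotype_names]
    lengths = np.array([len(h) for h in haps])
    n_pairs = int(round(params.coverage * lengths.mean() / (2 * rl)))

    hap_idx = rng.integers(0, len(haps), n_pairs)
    ins = np.rint(rng.normal(params.insert_size, params.insert_sigma, n_pairs)).astype(int)
    ins = np.clip(ins, rl, lengths[hap_idx])
    start = (rng.random(n_pairs) * (lengths[hap_idx] - ins + 1)).astype(np.int64)
    flip = rng.integers(0, 2, n_pairs).astype(np.uint8)

    r1 = np.empty((n_pairs, rl), dtype=np.uint8)
    r2 = np.empty((n_pairs, rl), dtype=np.uint8)
    cols = np.arange(rl)
    for h, hap in enumerate(haps):
        sel = hap_idx == h
        if not sel.any():
            continue
        s = start[sel]
        e = s + ins[sel]
        fwd = hap[s[:, None] + cols]
        rev = 3 - hap[(e - rl)[:, None] + cols][:, ::-1]
        fl = flip[sel].astype(bool)
        r1[sel] = np.where(fl[:, None], rev, fwd)
        r2[sel] = np.where(fl[:, None], fwd, rev)

    if params.error_rate > 0:
        for mat in (r1, r2):
            m = rng.random(mat.shape) < params.error_rate
            shift = rng.integers(1, 4, int(m.sum())).astype(np.uint8)
            mat[m] = (mat[m] + shift) % 4

    return ReadSet(r1, r2, genome.haplotype_names, hap_idx, start, ins, flip)


def simulate_survey_pair(params: SimulationParams,
                         male_heterozygosity: float | None = None
                         ) -> tuple[DiploidGenome, DiploidGenome]:
    """A conspecific male (ZZ) and female (ZW) genome sharing one autosomal
    background, as a genome-survey study design requires.

    ``params`` describes the female; the male reuses the same background
    (same seed, ZZ, no W material, no Z loss) with its own heterozygosity.
    """
    female = simulate_diploid_genome(params)
    male_params = dataclasses.replace(
        params, sex_system="ZZ_male", w_segment_count=0, z_loss_bases=0,
        heterozygosity=(male_heterozygosity
                        if male_heterozygosity is not None
                        else params.heterozygosity))
    male = simulate_diploid_genome(male_params)
    return male, female


# ---------------------------------------------------------------------------
# mitogenomes

# canonical vertebrate mitochondrial complement: 13 CDS, 22 tRNA, 2 rRNA,
# 1 control region, with typical teleost gene lengths (total ~16.5 kb)
_MITO_LAYOUT = (
    [("tRNA-Phe", "tRNA", 70), ("12S-rRNA", "rRNA", 950), ("tRNA-Val", "tRNA", 70),
     ("16S-rRNA", "rRNA", 1680), ("tRNA-Leu1", "tRNA", 70),
     ("ND1", "CDS", 975), ("tRNA-Ile", "tRNA", 70), ("tRNA-Gln", "tRNA", 70),
     ("tRNA-Met", "tRNA", 70), ("ND2", "CDS", 1044), ("tRNA-Trp", "tRNA", 70),
     ("tRNA-Ala", "tRNA", 70), ("tRNA-Asn", "tRNA", 70), ("tRNA-Cys", "tRNA", 70),
     ("tRNA-Tyr", "tRNA", 70), ("COX1", "CDS", 1551), ("tRNA-Ser1", "tRNA", 70),
     ("tRNA-Asp", "tRNA", 70), ("COX2", "CDS", 690), ("tRNA-Lys", "tRNA", 70),
     ("ATP8", "CDS", 165), ("ATP6", "CDS", 684), ("COX3", "CDS", 786),
     ("tRNA-Gly", "tRNA", 70), ("ND3", "CDS", 348), ("tRNA-Arg", "tRNA", 70),
     ("ND4L", "CDS", 294), ("ND4", "CDS", 1380), ("tRNA-His", "tRNA", 70),
     ("tRNA-Ser2", "tRNA", 70), ("tRNA-Leu2", "tRNA", 70), ("ND5", "CDS", 1836),
     ("ND6", "CDS", 522), ("tRNA-Glu", "tRNA", 70), ("CYTB", "CDS", 1141),
     ("tRNA-Thr", "tRNA", 70), ("tRNA-Pro", "tRNA", 70)]
)
_MITO_GC = 0.43


def simulate_mitogenome_set(n_taxa: int, guide_tree: PhyloTree | None = None,
                            subs_rate: float = 1.0, seed: int = 0):
    """Annotated ~16.5-kb circular mitogenomes diverged along ``guide_tree``.

    Each branch substitutes every site independently with probability
    ``branch_length * subs_rate``.  Returns a list of ``MitoGenome`` records
    (one per leaf, in leaf order) all sharing the same annotation layout.
    """
    from .mito import MitoGenome

    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = np.random.default_rng([seed, 2])
    if guide_tree is None:
        guide_tree = random_tree([f"taxon{i+1}" for i in range(n_taxa)], rng)
    if guide_tree.n_leaves != n_taxa:
        raise ValueError(
            f"guide tree has {guide_tree.n_leaves} leaves, expected {n_taxa}")

    dloop_len = int(930 + rng.integers(-250, 251))
    layout = list(_MITO_LAYOUT) + [("D-loop", "D-loop", dloop_len)]
    total = sum(l for _, _, l in layout)
    root_seq = _exact_composition(total, _MITO_GC, rng)

    features = []
    pos = 0
    for name, kind, ln in layout:
        features.append((name, kind, pos, pos + ln))
        pos += ln

    leaves: dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, seq: np.ndarray):
        p = min(1.0, node.length * subs_rate)
        if p > 0:
            m = rng.random(seq.size) < p
            seq = seq.copy()
            shift = rng.integers(1, 4, int(m.sum())).astype(np.uint8)
            seq[m] = (seq[m] + shift) % 4
        if node.is_leaf:
            leaves[node.name] = seq
        else:
            for c in node.children:
                evolve(c, seq)

    for child in guide_tree.root.children:
        evolve(child, root_seq)
    # the root itself has no incoming branch

    return [MitoGenome(name=label, seq=leaves[label], features=list(features),
                       circular=True)
            for label in guide_tree.leaf_labels()]
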