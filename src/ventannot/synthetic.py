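"""Synthetic inputs with planted ground truth.

Emulates the inputs of a 454 gill-transcriptome annotation run: contigs
with planted ORFs drawn from a configurable codon-usage table, flanking
UTRs, 3' poly-A tails, terminal adapter contamination and a sprinkle of
ambiguity characters; ranked homology-hit tables with E-values growing
with rank, BLASTx frames and subject taxids; a small multi-root ontology
DAG; and a small rooted taxonomy with Bacteria and Eukaryota
superkingdoms. Fixed seed implies byte-identical outputs.

Default condition: 1,000 contigs, half coding (the study translated
roughly half its contigs), strict/relaxed/no-hit tier mix 0.47/0.09/0.44
matching the published tier proportions, 25 ranked hits at most per
query, 16% bacterial sources (3,522 bacterial contigs of 22,023 with
protein matches), 5% hit-frame noise.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .frames import (AA_FAMILIES, CODONS, STOP_CODONS, reverse_complement)
from .io import HIT_COLUMNS
from .ontology import NAMESPACES, OntologyDag
from .preprocess import Contig
from .taxonomy import SUPERKINGDOM, TaxonNode, TaxonomyTable

# canonical SMART IIA oligonucleotide
DEFAULT_ADAPTER = "AAGCAGTGGTATCAACGCAGAGT"

SENSE_AAS = sorted(set(AA_FAMILIES) - {"*"})


def default_codon_usage() -> dict[str, float]:
    """A deterministically skewed usage table: within each synonymous
    family, codons (alphabetical) get geometrically decaying weights.
    Entries sum to 1 within each amino-acid family."""
    usage: dict[str, float] = {}
    for fam in AA_FAMILIES.values():
        weights = np.array([2.0 ** -i for i in range(len(fam))])
        weights /= weights.sum()
        for codon, w in zip(sorted(fam), weights):
            usage[codon] = float(w)
    return usage


def joint_codon_frequencies(usage: dict[str, float]) -> dict[str, float]:
    """The joint codon distribution an emitted ORF body follows: a
    uniform amino-acid marginal over the 20 sense families times the
    within-family usage weights; stop codons carry mass 0 (they never
    appear inside the stop-free body). Sums to 1 over the 64 codons."""
    joint = {}
    for aa, fam in AA_FAMILIES.items():
        for codon in fam:
            joint[codon] = 0.0 if aa == "*" \
                else usage[codon] / len(SENSE_AAS)
    return joint


def uniform_codon_usage() -> dict[str, float]:
    usage: dict[str, float] = {}
    for fam in AA_FAMILIES.values():
        for codon in fam:
            usage[codon] = 1.0 / len(fam)
    return usage


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic run (all generators derive
    their streams from ``seed``)."""

    seed: int = 0
    n_contigs: int = 1000
    coding_fraction: float = 0.5
    codon_usage: dict[str, float] = field(default_factory=default_codon_usage)
    utr_length_range: tuple[int, int] = (20, 120)
    polya_rate: float = 0.35
    adapter_sequence: str = DEFAULT_ADAPTER
    adapter_rate: float = 0.3
    bacterial_fraction: float = 0.16
    hit_depth: int = 25
    evalue_decay: float = 0.8
    # tier mix among coding contigs (remainder receives no hits)
    strict_fraction: float = 0.47
    relaxed_fraction: float = 0.09
    frame_noise: float = 0.05
    orf_codon_range: tuple[int, int] = (80, 200)
    noncoding_length_range: tuple[int, int] = (150, 900)
    n_rate: float = 0.001  # ambiguity-character injection
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def validate(self) -> None:
        for name in ("coding_fraction", "polya_rate", "adapter_rate",
                     "bacterial_fraction", "strict_fraction",
                     "relaxed_fraction", "frame_noise", "n_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.strict_fraction + self.relaxed_fraction > 1.0 + 1e-12:
            raise ConfigError("strict_fraction + relaxed_fraction exceeds 1")
        if not self.codon_usage:
            raise ConfigError("codon_usage table is empty")
        if set(self.codon_usage) != set(CODONS):
            raise ConfigError("codon_usage must cover all 64 codons")
        if any(v < 0 for v in self.codon_usage.values()):
            raise ConfigError("codon_usage entries must be non-negative")
        for fam in AA_FAMILIES.values():
            s = sum(self.codon_usage[c] for c in fam)
            if not math.isclose(s, 1.0, abs_tol=1e-6):
                raise ConfigError(
                    f"codon_usage family for {fam} sums to {s}, expected 1")
        if self.utr_length_range[0] < 0 or \
                self.utr_length_range[1] < self.utr_length_range[0]:
            raise ConfigError(f"bad utr_length_range {self.utr_length_range}")
        if self.hit_depth < 1:
            raise ConfigError("hit_depth must be >= 1")
        if self.evalue_decay <= 0:
            raise ConfigError("evalue_decay must be positive")
        if not math.isclose(sum(self.background), 1.0, abs_tol=1e-9):
            raise ConfigError("background base frequencies must sum to 1")


@dataclass
class GroundTruth:
    """Planted truth per contig: frame (0 = non-coding), coding interval
    (0-based half-open, in the emitted sequence's coordinates), source
    superkingdom, GO leaf assignments."""

    frames: dict[str, int] = field(default_factory=dict)
    intervals: dict[str, Optional[tuple[int, int]]] = field(default_factory=dict)
    superkingdoms: dict[str, Optional[str]] = field(default_factory=dict)
    go_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def coding_ids(self) -> list[str]:
        return [cid for cid, f in self.frames.items() if f != 0]

    def shifted(self, contig_id: str, removed_prefix: int,
                removed_suffix: int, old_length: int) -> None:
        """Lift frame and interval onto trimmed coordinates (used after
        adapter removal; the planted ORF always lies inside the insert)."""
        if self.frames.get(contig_id, 0) == 0:
            return
        s, e = self.intervals[contig_id]
        new_len = old_length - removed_prefix - removed_suffix
        s, e = s - removed_prefix, e - removed_prefix
        self.intervals[contig_id] = (s, e)
        if self.frames[contig_id] > 0:
            self.frames[contig_id] = (s % 3) + 1
        else:
            self.frames[contig_id] = -(((new_len - e) % 3) + 1)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in sorted(self.frames):
            iv = self.intervals.get(cid)
            rows.append((
                cid, self.frames[cid],
                iv[0] if iv else -1, iv[1] if iv else -1,
                self.superkingdoms.get(cid) or "",
                ";".join(self.go_terms.get(cid, ())),
            ))
        return pd.DataFrame(rows, columns=[
            "contig_id", "frame", "cds_start", "cds_end",
            "superkingdom", "go_terms"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _random_bases(rng: np.random.Generator, n: int,
                  background: Sequence[float]) -> str:
    idx = rng.choice(4, size=n, p=np.asarray(background))
    lut = np.array(list("ACGT"))
    return "".join(lut[idx])


class _UsageSampler:
    """Sample codons: amino acid uniform over the 20 sense families, then
    a codon within the family by the usage weights."""

    def __init__(self, usage: dict[str, float]):
        self.fams = {}
        for aa, fam in AA_FAMILIES.items():
            codons = sorted(fam)
            w = np.array([usage[c] for c in codons], dtype=float)
            w = w / w.sum()
            self.fams[aa] = (codons, w)

    def sample_codons(self, rng: np.random.Generator, n: int) -> list[str]:
        aas = rng.choice(SENSE_AAS, size=n)
        out = []
        for aa in aas:
            codons, w = self.fams[aa]
            out.append(codons[rng.choice(len(codons), p=w)])
        return out

    def sample_stop(self, rng: np.random.Generator) -> str:
        codons, w = self.fams["*"]
        return codons[rng.choice(len(codons), p=w)]


def simulate_contigs(config: SimulationConfig,
                     ) -> tuple[list[Contig], GroundTruth]:
    """Generate contigs with planted ORFs and the matching ground truth.

    Coding contigs carry a 5'UTR + ATG...stop ORF + 3'UTR, on either
    strand; a ``polya_rate`` fraction carry a 3' A-run (a 5' T-run after
    reverse-complementing); an ``adapter_rate`` fraction carry the
    adapter at each end independently.
    """
    config.validate()
    rng = np.random.default_rng([0, config.seed])
    sampler = _UsageSampler(config.codon_usage)
    contigs: list[Contig] = []
    truth = GroundTruth()
    width = len(str(config.n_contigs))

    for i in range(config.n_contigs):
        cid = f"contig{i + 1:0{width}d}"
        coding = rng.random() < config.coding_fraction
        if coding:
            n_cod = int(rng.integers(config.orf_codon_range[0],
                                     config.orf_codon_range[1] + 1))
            orf = "ATG" + "".join(sampler.sample_codons(rng, n_cod)) \
                + sampler.sample_stop(rng)
            u5 = int(rng.integers(config.utr_length_range[0],
                                  config.utr_length_range[1] + 1))
            u3 = int(rng.integers(config.utr_length_range[0],
                                  config.utr_length_range[1] + 1))
            transcript = (_random_bases(rng, u5, config.background) + orf
                          + _random_bases(rng, u3, config.background))
            cds = (u5, u5 + len(orf))
        else:
            length = int(rng.integers(config.noncoding_length_range[0],
                                      config.noncoding_length_range[1] + 1))
            transcript = _random_bases(rng, length, config.background)
            cds = None

        if rng.random() < config.polya_rate:
            transcript += "A" * int(rng.integers(15, 31))

        reverse = bool(rng.random() < 0.5)
        body = reverse_complement(transcript) if reverse else transcript
        pre = config.adapter_sequence if rng.random() < config.adapter_rate \
            else ""
        post = config.adapter_sequence if rng.random() < config.adapter_rate \
            else ""
        seq = pre + body + post

        if config.n_rate > 0:
            arr = np.frombuffer(seq.encode(), dtype="S1").copy()
            hitmask = rng.random(len(arr)) < config.n_rate
            arr[hitmask] = b"N"
            seq = arr.tobytes().decode()

        if cds is None:
            frame, interval, sk = 0, None, None
        else:
            length_orf = cds[1] - cds[0]
            if not reverse:
                start = len(pre) + cds[0]
                frame = (start % 3) + 1
            else:
                start = len(pre) + (len(transcript) - cds[1])
                frame = -(((len(seq) - (start + length_orf)) % 3) + 1)
            interval = (start, start + length_orf)
            sk = ("Bacteria" if rng.random() < config.bacterial_fraction
                  else "Eukaryota")

        rc_draw = rng.random()
        read_count = 1 if rc_draw < 0.04 else (
            2 if rc_draw < 0.43 else 3 + int(rng.geometric(0.25)))
        contigs.append(Contig(id=cid, sequence=seq, read_count=read_count))
        truth.frames[cid] = frame
        truth.intervals[cid] = interval
        truth.superkingdoms[cid] = sk

    return contigs, truth


def simulate_hits(contigs: Sequence[Contig], truth: GroundTruth,
                  config: SimulationConfig,
                  taxonomy: Optional[TaxonomyTable] = None) -> pd.DataFrame:
    """Ranked homology-hit table for coding contigs.

    Per coding contig a tier is drawn (strict / relaxed / no hits) with
    the configured mix; E-values start below the tier's cutoff and grow
    with rank (exponential-family increments, rate ``evalue_decay``);
    each hit's frame matches the planted frame except with probability
    ``frame_noise``; contigs from a bacterial source get their best
    bacterial hit at a low rank, eukaryotic contigs get none.
    """
    config.validate()
    rng = np.random.default_rng([1, config.seed])
    if taxonomy is None:
        taxonomy = simulate_taxonomy(seed=config.seed)
    bact_leaves = taxonomy.leaves("Bacteria")
    euk_leaves = taxonomy.leaves("Eukaryota")
    if not bact_leaves or not euk_leaves:
        raise ConfigError("taxonomy lacks Bacteria or Eukaryota leaves")

    rows = []
    subject = 0
    other = {f: [g for g in (1, 2, 3, -1, -2, -3) if g != f]
             for f in (1, 2, 3, -1, -2, -3)}
    for contig in contigs:
        frame = truth.frames.get(contig.id, 0)
        if frame == 0:
            continue
        u = rng.random()
        if u < config.strict_fraction:
            best_exp = rng.uniform(7.0, 30.0)
        elif u < config.strict_fraction + config.relaxed_fraction:
            best_exp = rng.uniform(2.1, 5.9)
        else:
            continue  # no hits: left for the coding scan

        k = int(rng.integers(5, config.hit_depth + 1))
        increments = rng.exponential(config.evalue_decay, size=k)
        increments[0] = 0.0
        exponents = -best_exp + np.cumsum(increments)
        evalues = np.minimum(10.0 ** exponents, 1e3)

        bacterial = truth.superkingdoms.get(contig.id) == "Bacteria"
        taxa = list(rng.choice(euk_leaves, size=k))
        if bacterial:
            best_bact = min(int(rng.geometric(0.3)), 12, k)
            for r in range(best_bact, k + 1):
                if r == best_bact or rng.random() < 0.5:
                    taxa[r - 1] = int(rng.choice(bact_leaves))

        bit0 = rng.uniform(80.0, 300.0)
        for r in range(1, k + 1):
            subject += 1
            hit_frame = frame if rng.random() >= config.frame_noise \
                else int(rng.choice(other[frame]))
            aln = int(rng.integers(30, 200))
            pident = float(np.round(rng.uniform(35.0, 98.0), 2))
            mismatch = int(round(aln * (1 - pident / 100.0)))
            bit = max(25.0, bit0 * math.exp(-0.05 * (r - 1))
                      + rng.normal(0, 2.0))
            qstart = 1
            qend = qstart + 3 * aln - 1
            rows.append((contig.id, f"sbj{subject:07d}", pident, aln,
                         mismatch, 0, qstart, qend, 1, aln,
                         float(evalues[r - 1]), float(np.round(bit, 1)),
                         hit_frame, int(taxa[r - 1])))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def simulate_ontology(n_terms: int = 120, max_parents: int = 2,
                      seed: int = 0) -> OntologyDag:
    """A random multi-root is_a DAG.

    The three namespace roots always exist; every further term gets 1 to
    ``max_parents`` parents drawn from already-created terms of the same
    namespace, which guarantees acyclicity and single-root reachability.
    """
    if n_terms < 3:
        raise ConfigError("n_terms must be >= 3 (three namespace roots)")
    if max_parents < 1:
        raise ConfigError("max_parents must be >= 1")
    rng = np.random.default_rng([2, seed])
    graph = nx.DiGraph()
    root_ids = {"biological_process": "GO:0008150",
                "molecular_function": "GO:0003674",
                "cellular_component": "GO:0005575"}
    by_ns: dict[str, list[str]] = {ns: [] for ns in NAMESPACES}
    for ns in NAMESPACES:
        tid = root_ids[ns]
        graph.add_node(tid, name=ns.replace("_", " "), namespace=ns)
        by_ns[ns].append(tid)
    for i in range(n_terms - 3):
        ns = NAMESPACES[int(rng.integers(3))]
        tid = f"GO:{7000000 + i:07d}"
        graph.add_node(tid, name=f"synthetic term {i}", namespace=ns)
        pool = by_ns[ns]
        n_par = int(rng.integers(1, min(max_parents, len(pool)) + 1))
        parents = rng.choice(len(pool), size=n_par, replace=False)
        for p in parents:
            graph.add_edge(tid, pool[int(p)])
        by_ns[ns].append(tid)
    return OntologyDag(graph=graph)


def simulate_taxonomy(depth: int = 4, breadth: int = 3,
                      seed: int = 0) -> TaxonomyTable:
    """A rooted taxonomy tree with Bacteria and Eukaryota superkingdoms
    and ``depth`` ranked levels below them (2..breadth children each)."""
    if depth < 1 or breadth < 2:
        raise ConfigError("need depth >= 1 and breadth >= 2")
    rng = np.random.default_rng([3, seed])
    ranks = ["phylum", "class", "order", "family", "genus", "species"]
    if depth > len(ranks):
        raise ConfigError(f"depth must be <= {len(ranks)}")
    nodes = {1: TaxonNode(parent=1, rank="no rank", name="root"),
             2: TaxonNode(parent=1, rank=SUPERKINGDOM, name="Bacteria"),
             3: TaxonNode(parent=1, rank=SUPERKINGDOM, name="Eukaryota")}
    next_id = 4
    level = [2, 3]
    for d in range(depth):
        new_level = []
        for parent in level:
            for _ in range(int(rng.integers(2, breadth + 1))):
                nodes[next_id] = TaxonNode(
                    parent=parent, rank=ranks[d],
                    name=f"taxon {next_id} ({ranks[d]})")
                new_level.append(next_id)
                next_id += 1
        level = new_level
    return TaxonomyTable(nodes=nodes)


def simulate_go_assignments(truth: GroundTruth, dag: OntologyDag,
                            seed: int = 0,
                            terms_range: tuple[int, int] = (1, 3),
                            ) -> pd.DataFrame:
    """Assign 1-3 random ontology leaves to each coding contig, recorded
    both in the truth object and as a (product_id, term_id) table."""
    rng = np.random.default_rng([4, seed])
    leaves = sorted(dag.leaves())
    if not leaves:
        raise ConfigError("ontology has no leaf terms to assign")
    rows = []
    for cid in truth.coding_ids():
        n = int(rng.integers(terms_range[0], terms_range[1] + 1))
        chosen = rng.choice(len(leaves), size=min(n, len(leaves)),
                            replace=False)
        terms = tuple(leaves[int(i)] for i in sorted(chosen))
        truth.go_terms[cid] = terms
        rows.extend((cid, t) for t in terms)
    return pd.DataFrame(rows, columns=["product_id", "term_id"])


def adjust_truth_for_trimming(truth: GroundTruth, contigs: Sequence[Contig],
                              trim_offsets: dict[str, tuple[int, int]],
                              ) -> GroundTruth:
    """Ground truth lifted onto post-trimming coordinates."""
    lifted = GroundTruth(frames=dict(truth.frames),
                         intervals=dict(truth.intervals),
                         superkingdoms=dict(truth.superkingdoms),
                         go_terms=dict(truth.go_terms))
    lengths = {c.id: len(c.sequence) for c in contigs}
    for cid, (pre, post) in trim_offsets.items():
        if pre or post:
            lifted.shifted(cid, pre, post, lengths[cid])
    return lifted
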