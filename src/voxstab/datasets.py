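"""Labeled mutation tables and dataset curation.

Covers the curation steps around training: anti-symmetric augmentation
(every direct X->Y record gains a reverse Y->X record with the negated ddG),
homology pruning between training and test proteins by global-alignment
percent identity, and the paired k-subset split that keeps each direct
record and its reverse in the same subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .chem import AA_1TO3

logger = logging.getLogger(__name__)

TABLE_COLUMNS = [
    "wt_structure", "mut_structure", "chain", "position",
    "wt_aa", "mut_aa", "ddg", "direction", "pair_id",
]


@dataclass(frozen=True)
class MutationRecord:
    """One labeled point mutation between a wild-type/mutant structure pair."""

    wt_structure: str
    mut_structure: str
    chain: str
    position: int
    wt_aa: str
    mut_aa: str
    ddg: float | None = None
    direction: str = "direct"
    pair_id: str = ""

    def __post_init__(self):
        for aa, role in ((self.wt_aa, "wt_aa"), (self.mut_aa, "mut_aa")):
            if aa not in AA_1TO3:
                raise ValueError(f"invalid amino-acid code {aa!r} in {role}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(
                f"wt and mutant amino acid are both {self.wt_aa!r}; not a mutation"
            )
        if self.direction not in ("direct", "reverse"):
            raise ValueError(f"direction must be direct/reverse, got {self.direction!r}")

    @property
    def key(self) -> tuple:
        return (self.wt_structure, self.chain, self.position, self.wt_aa, self.mut_aa)

    def reversed(self) -> "MutationRecord":
        """The thermodynamic reverse: swapped roles, exactly negated ddG."""
        if self.ddg is None:
            raise ValueError("cannot reverse a record without a ddG label")
        return replace(
            self,
            wt_structure=self.mut_structure,
            mut_structure=self.wt_structure,
            wt_aa=self.mut_aa,
            mut_aa=self.wt_aa,
            ddg=-self.ddg,
            direction="reverse" if self.direction == "direct" else "direct",
        )


@dataclass
class MutationTable:
    """Ordered list of mutation records with duplicate/pairing invariants."""

    records: list[MutationRecord] = field(default_factory=list)
    source: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "wt_structure": r.wt_structure, "mut_structure": r.mut_structure,
                "chain": r.chain, "position": r.position,
                "wt_aa": r.wt_aa, "mut_aa": r.mut_aa,
                "ddg": np.nan if r.ddg is None else r.ddg,
                "direction": r.direction, "pair_id": r.pair_id,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=TABLE_COLUMNS)

    def validate(self):
        seen: set[tuple] = set()
        for r in self.records:
            if r.key in seen:
                raise ValueError(f"duplicate mutation entry {r.key}")
            seen.add(r.key)


def read_table(path) -> MutationTable:
    """Read a tab-separated mutation table; rows are validated individually."""
    df = pd.read_csv(path, sep="\t", dtype={"chain": str, "pair_id": str},
                     float_precision="round_trip")
    missing = [c for c in TABLE_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table {path} lacks columns: {missing}")
    records, errors = [], []
    for i, row in df.iterrows():
        try:
            ddg = row.get("ddg", np.nan)
            ddg = None if pd.isna(ddg) else float(ddg)
            records.append(MutationRecord(
                wt_structure=str(row["wt_structure"]),
                mut_structure=str(row["mut_structure"]),
                chain=str(row["chain"]),
                position=int(row["position"]),
                wt_aa=str(row["wt_aa"]),
                mut_aa=str(row["mut_aa"]),
                ddg=ddg,
                direction=str(row.get("direction", "direct") or "direct"),
                pair_id="" if pd.isna(row.get("pair_id", "")) else str(row.get("pair_id", "")),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"row {i + 2}: {exc}")  # +2: header + 1-based
    if errors:
        raise ValueError(
            f"{len(errors)} invalid row(s) in {path}:\n" + "\n".join(errors)
        )
    table = MutationTable(records=records, source=str(path))
    table.validate()
    return table


def write_table(table: MutationTable, path):
    # %.17g keeps ddg round trips bit-exact
    table.to_frame().to_csv(path, sep="\t", index=False, na_rep="",
                            float_format="%.17g")


def dedupe(table: MutationTable) -> MutationTable:
    """Keep the first occurrence of each (structure, chain, pos, wt, mut)."""
    seen: set[tuple] = set()
    kept = []
    for r in table.records:
        if r.key in seen:
            logger.info("dropping duplicate mutation %s", r.key)
            continue
        seen.add(r.key)
        kept.append(r)
    return MutationTable(records=kept, source=table.source)


def augment_reverse(table: MutationTable) -> MutationTable:
    """Add the reverse mutation for every direct record (anti-symmetry).

    The input must contain direct records only, all with ddG labels; the
    output interleaves each direct record with its reverse partner sharing a
    pair id, so n records become exactly 2n.
    """
    out: list[MutationRecord] = []
    for i, r in enumerate(table.records):
        if r.direction != "direct":
            raise ValueError("table already contains reverse records; cannot augment twice")
        if r.ddg is None:
            raise ValueError(f"record {r.key} has no ddG label; cannot build its reverse")
        pair_id = r.pair_id or f"pair{i:06d}"
        direct = replace(r, pair_id=pair_id)
        out.append(direct)
        out.append(direct.reversed())
    return MutationTable(records=out, source=table.source)


def split_subsets(table: MutationTable, k: int = 10, seed: int = 0) -> list[list[int]]:
    """Partition a fully paired table into ``k`` subsets of whole pairs.

    Each direct record and its reverse land in the same subset; subset sizes
    differ by at most one pair.  Deterministic in ``seed``.
    """
    by_pair: dict[str, list[int]] = {}
    for i, r in enumerate(table.records):
        if not r.pair_id:
            raise ValueError(f"record {i} has no pair_id; table is not paired")
        by_pair.setdefault(r.pair_id, []).append(i)
    for pid, idxs in by_pair.items():
        dirs = sorted(table.records[i].direction for i in idxs)
        if dirs != ["direct", "reverse"]:
            raise ValueError(f"pair {pid!r} is not a direct/reverse pair: {dirs}")
    pair_ids = list(by_pair)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pair_ids))
    subsets: list[list[int]] = [[] for _ in range(k)]
    for slot, j in enumerate(order):
        subsets[slot % k].extend(by_pair[pair_ids[j]])
    return [sorted(s) for s in subsets]


# -- sequence identity and homology pruning ----------------------------------

def _aligner(open_gap: float = -10.0, extend_gap: float = -0.5):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def pairwise_identity(seq_a: str, seq_b: str,
                      open_gap: float = -10.0, extend_gap: float = -0.5) -> float:
    """Percent sequence identity from a global alignment.

    Identity = identical aligned columns / alignment length (gaps included)
    x 100, under BLOSUM62 scoring with affine gaps.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(open_gap, extend_gap)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a, b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    return 100.0 * matches / len(a)


@dataclass
class HomologyClusters:
    """Single-linkage clusters over an identity matrix at a threshold."""

    ids: list[str]
    identity: np.ndarray  # (n, n) percent
    threshold: float
    clusters: list[set[str]]


def cluster_homologs(seqs: dict[str, str], threshold: float = 25.0) -> HomologyClusters:
    """Single-linkage clustering of sequences at a percent-identity threshold."""
    ids = list(seqs)
    n = len(ids)
    mat = np.full((n, n), 100.0)
    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i in range(n):
        for j in range(i + 1, n):
            ident = pairwise_identity(seqs[ids[i]], seqs[ids[j]])
            mat[i, j] = mat[j, i] = ident
            if ident >= threshold:
                graph.add_edge(ids[i], ids[j])
    clusters = [set(c) for c in nx.connected_components(graph)]
    return HomologyClusters(ids=ids, identity=mat, threshold=threshold, clusters=clusters)


@dataclass
class PruneResult:
    retained: list[str]
    removed: list[str]
    train_clusters: list[set[str]]


def prune_homologs(train_seqs: dict[str, str], test_seqs: dict[str, str],
                   threshold: float = 25.0) -> PruneResult:
    """Drop training proteins homologous to any test protein.

    A training sequence is removed when its global-alignment percent
    identity to any test sequence reaches ``threshold`` (default 25%).
    Within-train single-linkage clusters are reported for leakage audits.
    """
    collisions = set(train_seqs) & set(test_seqs)
    if collisions:
        raise ValueError(f"ids present in both train and test sets: {sorted(collisions)}")
    retained, removed = [], []
    for tid, tseq in train_seqs.items():
        hom = any(
            pairwise_identity(tseq, qseq) >= threshold for qseq in test_seqs.values()
        )
        (removed if hom else retained).append(tid)
    kept = {tid: train_seqs[tid] for tid in retained}
    clusters = cluster_homologs(kept, threshold).clusters if kept else []
    return PruneResult(retained=retained, removed=removed, train_clusters=clusters)


# -- FASTA I/O ---------------------------------------------------------------

def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path):
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
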