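"""Ground-truth epitope annotation and dataset-curation utilities.

An epitope is defined operationally from an antibody-antigen complex: an
antigen residue is epitopal iff any of its heavy atoms lies within a distance
cutoff (default 4.0 A) of any antibody heavy atom.  Annotations made on bound
complexes can be transferred to unbound antigen structures by global sequence
alignment.  Dataset-curation helpers implement resolution/length filters and
greedy sequence-identity redundancy removal.

Note: only the distance rule is implemented here; contact-legitimacy
classification (as done by dedicated contact-analysis programs) is a
deliberate non-goal.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial import cKDTree

from .structure import AntigenStructure, ResidueId, parse_structure

log = logging.getLogger(__name__)


@dataclass
class EpitopeAnnotation:
    antigen_id: str
    residues: set[ResidueId]
    source: str = "contact"  # "contact" | "transferred" | "file"

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class OverlapResult:
    percent_overlap: float  # in [0, 100]
    shared: set[ResidueId]


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    # terminal overhangs are free: bound/unbound constructs commonly differ
    # by expression tags or disordered termini
    aligner.end_gap_score = 0.0
    return aligner


def _align_stats(seq_a: str, seq_b: str):
    """Best global alignment: (a->b index map, identity).

    Identity = matches / alignment columns, end-gap columns excluded.
    """
    aln = _make_aligner().align(seq_a, seq_b)[0]
    blocks_a, blocks_b = aln.aligned
    mapping: dict[int, int] = {}
    matches = 0
    aligned_pairs = 0
    for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            mapping[i] = j
            if seq_a[i] == seq_b[j]:
                matches += 1
        aligned_pairs += a1 - a0
    if aligned_pairs == 0:
        return mapping, 0.0
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    columns = span_a + span_b - aligned_pairs
    return mapping, matches / columns


def sequence_identity(seq_a: str, seq_b: str) -> float:
    """Fractional identity under global alignment (end gaps excluded)."""
    return _align_stats(seq_a, seq_b)[1]


def extract_epitope(
    complex_path: str | Path | None = None,
    antigen_chains: list[str] | str | None = None,
    antibody_chains: list[str] | str | None = None,
    cutoff: float = 4.0,
    *,
    antigen: AntigenStructure | None = None,
    antibody: AntigenStructure | None = None,
    antigen_id: str | None = None,
) -> EpitopeAnnotation:
    """Annotate epitopal residues of an antigen in an antibody-antigen complex.

    An antigen residue is included iff the minimum heavy-atom distance to the
    antibody is <= ``cutoff`` (A).  Either give a complex PDB file plus the two
    chain groups, or pre-parsed ``antigen``/``antibody`` structures.
    """
    if antigen is None or antibody is None:
        if complex_path is None:
            raise ValueError("need either a complex file or parsed structures")
        if isinstance(antigen_chains, str):
            antigen_chains = antigen_chains.split(",")
        if isinstance(antibody_chains, str):
            antibody_chains = antibody_chains.split(",")
        if not antigen_chains or not antibody_chains:
            raise ValueError("both chain groups must be non-empty")
        if set(antigen_chains) & set(antibody_chains):
            raise ValueError("antigen and antibody chain groups overlap")
        antigen = parse_structure(complex_path, antigen_chains)
        antibody = parse_structure(complex_path, antibody_chains)
        antigen_id = antigen_id or Path(complex_path).stem

    ab_atoms = np.vstack(antibody.coords)
    tree = cKDTree(ab_atoms)
    epitopal: set[ResidueId] = set()
    for rid, xyz in zip(antigen.residues, antigen.coords):
        d, _ = tree.query(xyz, k=1)
        if np.min(d) <= cutoff:
            epitopal.add(rid)
    if not epitopal:
        warnings.warn(
            f"no antigen-antibody contacts within {cutoff} A for "
            f"{antigen_id!r}; check the chain assignment")
    return EpitopeAnnotation(antigen_id or "antigen", epitopal, source="contact")


def transfer_annotation(
    bound_annotation: EpitopeAnnotation,
    bound: AntigenStructure,
    unbound: AntigenStructure,
    min_identity: float = 0.95,
) -> EpitopeAnnotation:
    """Map a bound-complex annotation onto an unbound antigen structure.

    The two sequences are globally aligned; each epitopal position maps to its
    aligned unbound residue.  Positions aligned to a gap are dropped with a
    warning.  Refuses to transfer below ``min_identity`` (default 95%, the
    bound/unbound pairing criterion).
    """
    mapping, identity = _align_stats(bound.sequence(), unbound.sequence())
    if identity < min_identity:
        raise ValueError(
            f"sequence identity {identity:.2%} below the "
            f"{min_identity:.0%} transfer threshold")
    bound_pos = bound.index()
    transferred: set[ResidueId] = set()
    for rid in bound_annotation.residues:
        i = bound_pos[rid.key]
        j = mapping.get(i)
        if j is None:
            log.warning("epitopal residue %s aligns to a gap; dropped", rid)
            continue
        transferred.add(unbound.residues[j])
    return EpitopeAnnotation(bound_annotation.antigen_id, transferred,
                             source="transferred")


def epitope_overlap(
    a: EpitopeAnnotation | set,
    b: EpitopeAnnotation | set,
    denominator: str = "union",
) -> OverlapResult:
    """Percentage of identical residues between two epitopes.

    ``denominator="union"`` gives the Jaccard-style percentage
    100*|a&b|/|a|b|; ``"min"`` normalizes by the smaller set.  Both choices
    agree at the 0% (disjoint) and 100% (identical) endpoints.
    """
    set_a = a.residues if isinstance(a, EpitopeAnnotation) else set(a)
    set_b = b.residues if isinstance(b, EpitopeAnnotation) else set(b)
    shared = set_a & set_b
    if not set_a and not set_b:
        warnings.warn("overlap of two empty epitope annotations")
        return OverlapResult(0.0, set())
    if denominator == "union":
        denom = len(set_a | set_b)
    elif denominator == "min":
        denom = min(len(set_a), len(set_b)) or 1
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return OverlapResult(100.0 * len(shared) / denom, shared)


def redundancy_filter(
    sequences: dict[str, str],
    identity_threshold: float = 0.30,
) -> list[str]:
    """Greedy redundancy removal at a pairwise-identity threshold.

    Sequences are processed longest-first; one joins an existing cluster when
    its identity to that cluster's representative exceeds the threshold,
    otherwise it founds a new cluster.  Returns the representative ids.
    """
    if not sequences:
        raise ValueError("no sequences given")
    order = sorted(sequences, key=lambda k: (-len(sequences[k]), k))
    representatives: list[str] = []
    for sid in order:
        seq = sequences[sid]
        if not any(sequence_identity(seq, sequences[rep]) > identity_threshold
                   for rep in representatives):
            representatives.append(sid)
    return representatives


def complex_filter(
    resolution: float | None,
    antigen_length: int | None,
    max_resolution: float = 3.0,
    min_length: int = 100,
    max_length: int = 450,
) -> bool:
    """Dataset inclusion rule: resolution < 3.0 A (strict) and length bounds.

    The default length window is 100-450 residues; pass
    ``min_length=61, max_length=None``-style overrides for the looser
    ">60 residues" variant used when mining bound complexes.
    """
    if resolution is None or antigen_length is None:
        warnings.warn("missing resolution or antigen length; complex rejected")
        return False
    if resolution >= max_resolution:
        return False
    if antigen_length < min_length:
        return False
    if max_length is not None and antigen_length > max_length:
        return False
    return True
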