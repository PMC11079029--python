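"""Proline-rich motif decomposition, peptide classification and scanning.

WW domains read short proline motifs (PPxP, PPLP, polyproline tracts).  A
tandem of two WW domains prefers bipartite ligands: two proline stretches,
or — in the highest-affinity case — a PPLP motif bridged by a short spacer
to a long polyproline run.  This module decomposes sequences into maximal
proline runs, assigns 16-mer-scale peptides to four affinity-ordered
classes, and scans protein sequences for candidate WW-ligand regions.

Coordinates are 1-based inclusive throughout, matching residue-numbering
conventions in the structural literature.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

from Bio import SeqIO

MotifKind = Literal["PPLP", "polyP_run", "bridge_PPxAP", "PPxP"]

PeptideClassName = Literal[
    "pplp_bridge_polyP", "two_stretches", "broken_stretch", "spaced"
]

#: motif regexes; PPxP covers both canonical orientations (PPxP and PxxPP)
MOTIF_PATTERNS: dict[str, str] = {
    "PPLP": r"PPLP",
    "polyP_run": r"P{4,}",
    "bridge_PPxAP": r"PP[^P]AP",
    "PPxP": r"PP[^P]P|P[^P][^P]PP",
}

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class ProlineDecomposition:
    sequence: str
    runs: list[tuple[int, int]]  # (start 1-based inclusive, length)
    proline_fraction: float


@dataclass
class MotifCall:
    kind: str
    start: int  # 1-based inclusive
    span: int
    detail: str


@dataclass
class PeptideClass:
    name: PeptideClassName
    rationale: str


def _check_sequence(seq: str) -> str:
    seq = seq.upper().strip()
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise ValueError(f"non-sequence characters {sorted(bad)}")
    return seq


def proline_runs(seq: str) -> ProlineDecomposition:
    """Maximal runs of consecutive prolines with 1-based coordinates."""
    seq = _check_sequence(seq)
    runs = [(m.start() + 1, m.end() - m.start()) for m in re.finditer(r"P+", seq)]
    frac = seq.count("P") / len(seq)
    return ProlineDecomposition(seq, runs, frac)


def find_motifs(seq: str, kinds: Iterable[str] | None = None) -> list[MotifCall]:
    """All motif matches (possibly overlapping across kinds) in order."""
    seq = _check_sequence(seq)
    calls = []
    for kind in kinds or MOTIF_PATTERNS:
        for m in re.finditer(MOTIF_PATTERNS[kind], seq):
            calls.append(
                MotifCall(kind, m.start() + 1, m.end() - m.start(), m.group())
            )
    calls.sort(key=lambda c: (c.start, c.kind))
    return calls


def classify_peptide(
    seq: str,
    min_run: int = 3,
    bridge_gap: int = 4,
    polyp_min: int = 4,
) -> PeptideClass:
    """Assign a peptide to one of four affinity-ordered classes.

    Priority order (mutually exclusive, first match wins):

    1. ``pplp_bridge_polyP`` — a PPLP motif followed, within at most
       ``bridge_gap`` non-proline residues, by a proline run of length >=
       ``polyp_min`` (the bipartite high-affinity architecture);
    2. ``two_stretches`` — at least two proline runs of length >= ``min_run``;
    3. ``broken_stretch`` — exactly one such run plus >= 2 further prolines
       outside it;
    4. ``spaced`` — everything else (isolated prolines; lowest affinity).
    """
    seq = _check_sequence(seq)
    if len(seq) < 8:
        warnings.warn("peptide shorter than 8 residues; classification is noisy")
    decomp = proline_runs(seq)
    for m in re.finditer(MOTIF_PATTERNS["PPLP"], seq):
        pplp_end = m.end()  # 0-based exclusive
        for start, length in decomp.runs:
            if length < polyp_min:
                continue
            run_start0 = start - 1
            if run_start0 < pplp_end:
                continue
            gap = seq[pplp_end:run_start0]
            if sum(1 for ch in gap if ch != "P") <= bridge_gap:
                return PeptideClass(
                    "pplp_bridge_polyP",
                    f"PPLP at {m.start() + 1} bridged to a {length}-proline "
                    f"run at {start}",
                )
    long_runs = [r for r in decomp.runs if r[1] >= min_run]
    if len(long_runs) >= 2:
        return PeptideClass(
            "two_stretches",
            f"{len(long_runs)} proline runs of length >= {min_run}",
        )
    if len(long_runs) == 1:
        outside = seq.count("P") - long_runs[0][1]
        if outside >= 2:
            return PeptideClass(
                "broken_stretch",
                f"one {long_runs[0][1]}-proline run plus {outside} prolines "
                "outside it",
            )
    return PeptideClass("spaced", "no or isolated short proline runs")


def proline_rich_regions(
    seq: str, window: int = 16, min_p: int = 8
) -> list[tuple[int, int]]:
    """Merged 1-based intervals where a window holds >= ``min_p`` prolines."""
    seq = _check_sequence(seq)
    if len(seq) < window:
        return []
    mask = [ch == "P" for ch in seq]
    count = sum(mask[:window])
    hits = []
    if count >= min_p:
        hits.append(0)
    for i in range(1, len(seq) - window + 1):
        count += mask[i + window - 1] - mask[i - 1]
        if count >= min_p:
            hits.append(i)
    intervals: list[tuple[int, int]] = []
    for start0 in hits:
        lo, hi = start0 + 1, start0 + window
        if intervals and lo <= intervals[-1][1] + 1:
            intervals[-1] = (intervals[-1][0], hi)
        else:
            intervals.append((lo, hi))
    return intervals


def scan_sequences(
    records: dict[str, str], window: int = 16, min_p: int = 8
) -> dict[str, dict]:
    """Motif calls, class and proline-rich intervals per named sequence.

    Records with non-sequence characters are skipped with a warning.
    """
    if not records:
        raise ValueError("no sequences to scan")
    out: dict[str, dict] = {}
    for name, seq in records.items():
        try:
            seq = _check_sequence(seq)
        except ValueError as err:
            warnings.warn(f"skipping record {name!r}: {err}")
            continue
        out[name] = {
            "motifs": find_motifs(seq),
            "regions": proline_rich_regions(seq, window, min_p),
            "class": classify_peptide(seq).name if len(seq) >= 8 else None,
            "proline_fraction": proline_runs(seq).proline_fraction,
        }
    return out


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# Sixteen-residue SF1-derived peptides used throughout the worked examples;
# keys give the SF1 residue span of each peptide.
SF1_PEPTIDES: dict[str, str] = {
    "SF1_342-357": "SAPRPAAPANNPPPPS",
    "SF1_387-402": "PGGPGGGPHSFPHPLP",
    "SF1_425-440": "MQPPPPPMNQGPHPPG",
    "SF1_470-485": "MPPPPMGMMPPPPPPP",
    "SF1_478-493": "MPPPPPPPSGQPPPPP",
    "SF1_565-580": "TMVPLPPGVQPPLPPG",
    "SF1_575-590": "PPLPPGAPPPPPPPPP",
    "SF1_596-611": "MYAPPPPPPPPMDPSN",
    "SF1_623-638": "MPPFGMPPAPPPPPPQ",
}

#: the high-affinity SF1 peptide recognized across both WW domains
SF1_WWBS = SF1_PEPTIDES["SF1_575-590"]
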