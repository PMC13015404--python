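"""Paralog-pair characterization and diagnostic k-mer screening.

When a sex-linked locus is a recently diverged duplicate of an autosomal
gene, conventional read mapping cannot attribute transcripts to one copy.
This module (1) aligns the two copies globally (affine gaps) and derives a
variant table of SNVs and indels between them; (2) detects premature stop
codons in the derived copy in a canonical-anchored reading frame; (3)
designs short diagnostic k-mers (default 24 bp) on the divergent copy
that span indel junctions and/or linked SNVs, differ from every
alternative locus by at least ``min_diff`` nucleotide differences and are
unique in the genome; and (4) screens RNA-seq libraries for these k-mers,
extracting and reconstructing matching read pairs and validating that
fragments carry multiple linked diagnostic variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd
from Bio import Align

from . import _dna

MATCH_SCORE = 1
MISMATCH_SCORE = -2
GAP_OPEN = -6  # first gap base costs GAP_OPEN + GAP_EXTEND
GAP_EXTEND = -1

STOP_CODONS = {"TAA", "TAG", "TGA"}
_IUPAC = set("ACGTRYSWKMBDHVN")


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = MATCH_SCORE
    al.mismatch_score = MISMATCH_SCORE
    # length-L gap costs GAP_OPEN + L * GAP_EXTEND
    al.open_gap_score = GAP_OPEN + GAP_EXTEND
    al.extend_gap_score = GAP_EXTEND
    return al


@dataclass
class ParalogAlignment:
    """Global pairwise alignment of canonical (A) vs derived (B) copy."""

    seq_a: str
    seq_b: str
    aligned_a: str  # gapped
    aligned_b: str
    score: float
    variants: pd.DataFrame  # kind, a_start, a_end, b_start, b_end, ref, alt

    def column_classes(self) -> list[str]:
        out = []
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca == "-":
                out.append("insertion")
            elif cb == "-":
                out.append("deletion")
            elif ca == cb:
                out.append("match")
            else:
                out.append("SNV")
        return out

    def project_exons(self, exons_a: list[tuple[int, int]]) -> pd.DataFrame:
        """Annotate each variant with the canonical exon it falls in
        (1-based exon number, 0 = intronic/intergenic)."""
        v = self.variants.copy()

        def _exon_of(a_pos):
            for i, (s, e) in enumerate(exons_a, 1):
                if s <= a_pos < e:
                    return i
            return 0

        v["exon_a"] = [_exon_of(p) for p in v["a_start"]]
        return v


def align_paralogs(seq_a: str, seq_b: str) -> ParalogAlignment:
    """Optimal global alignment (match +1, mismatch -2, gap -6 open,
    -1 extend) and the per-column variant table.

    Raises on characters outside the IUPAC nucleotide alphabet.
    """
    for name, s in (("A", seq_a), ("B", seq_b)):
        if not s:
            raise ValueError(f"sequence {name} is empty")
        bad = set(s.upper()) - _IUPAC
        if bad:
            raise ValueError(f"non-IUPAC characters in sequence {name}: {sorted(bad)}")
    aln = _aligner().align(seq_a, seq_b)[0]
    ga, gb = str(aln[0]), str(aln[1])
    variants = _variant_table(ga, gb)
    return ParalogAlignment(
        seq_a=seq_a,
        seq_b=seq_b,
        aligned_a=ga,
        aligned_b=gb,
        score=float(aln.score),
        variants=variants,
    )


def _variant_table(ga: str, gb: str) -> pd.DataFrame:
    """Collapse aligned columns into SNV / DEL / INS runs.

    Coordinates are 0-based half-open in the respective ungapped sequences;
    DEL = present in A absent in B, INS = present in B absent in A.
    For indels the *_start of the gapped sequence is the junction position.
    """
    rows = []
    a_pos = b_pos = 0
    i = 0
    n = len(ga)
    while i < n:
        ca, cb = ga[i], gb[i]
        if ca == "-" or cb == "-":
            kind = "INS" if ca == "-" else "DEL"
            j = i
            run_a, run_b = [], []
            while j < n and ((ga[j] == "-") if kind == "INS" else (gb[j] == "-")):
                if ga[j] != "-":
                    run_a.append(ga[j])
                if gb[j] != "-":
                    run_b.append(gb[j])
                j += 1
            rows.append(
                (
                    kind,
                    a_pos,
                    a_pos + len(run_a),
                    b_pos,
                    b_pos + len(run_b),
                    "".join(run_a),
                    "".join(run_b),
                )
            )
            a_pos += len(run_a)
            b_pos += len(run_b)
            i = j
        else:
            if ca != cb:
                rows.append(("SNV", a_pos, a_pos + 1, b_pos, b_pos + 1, ca, cb))
            a_pos += 1
            b_pos += 1
            i += 1
    return pd.DataFrame(
        rows, columns=["kind", "a_start", "a_end", "b_start", "b_end", "ref", "alt"]
    )


# ---------------------------------------------------------------------------
# premature stops


@dataclass(frozen=True)
class StopEvent:
    b_cds_pos: int  # codon start in derived CDS
    a_cds_pos: int  # aligned canonical CDS position of the codon start
    codon: str
    in_domain: bool
    frame_ambiguous: bool  # downstream of a frameshifting indel


def find_premature_stops(
    alignment: ParalogAlignment,
    domain_interval: tuple[int, int],
    frame: int = 0,
) -> list[StopEvent]:
    """Premature stop codons in the derived copy, canonical-anchored frame.

    Both sequences are taken as CDS (frame ``frame`` on the canonical
    copy).  Codons of the derived copy translating to a stop upstream of
    the canonical terminal stop are reported, annotated with overlap of
    ``domain_interval`` (canonical CDS bp, half-open).  Codons downstream
    of a frameshifting (length % 3 != 0) indel are flagged as
    frame-ambiguous because their canonical anchor is undefined.
    """
    b = alignment.seq_b
    # map derived position -> canonical position (or -1 inside insertions)
    b2a = np.full(len(b), -1, dtype=np.int64)
    a_pos = b_pos = 0
    for ca, cb in zip(alignment.aligned_a, alignment.aligned_b):
        if cb != "-":
            b2a[b_pos] = a_pos if ca != "-" else -1
            b_pos += 1
        if ca != "-":
            a_pos += 1
    # derived positions downstream of a frameshifting indel
    shift_from = len(b) + 1
    net = 0
    for _, v in alignment.variants.iterrows():
        if v["kind"] in ("DEL", "INS"):
            indel_len = (v["a_end"] - v["a_start"]) + (v["b_end"] - v["b_start"])
            if indel_len % 3 != 0:
                shift_from = min(shift_from, int(v["b_end"]))
    canonical_stop_a = len(alignment.seq_a) - 3
    out = []
    for cpos in range(frame, len(b) - 2, 3):
        codon = b[cpos : cpos + 3]
        if codon not in STOP_CODONS:
            continue
        a_anchor = int(b2a[cpos])
        if a_anchor >= canonical_stop_a and a_anchor != -1:
            continue  # the terminal stop itself
        lo, hi = domain_interval
        out.append(
            StopEvent(
                b_cds_pos=cpos,
                a_cds_pos=a_anchor,
                codon=codon,
                in_domain=a_anchor != -1 and lo <= a_anchor < hi,
                frame_ambiguous=cpos >= shift_from,
            )
        )
    return out


# ---------------------------------------------------------------------------
# diagnostic k-mer design


@dataclass
class DiagnosticKmer:
    """A short word uniquely identifying one paralog's transcripts."""

    sequence: str
    target_id: str
    start: int  # 0-based on the target
    end: int
    events: tuple[str, ...]  # event ids covered, e.g. ('DEL18@24', 'SNV@31')
    diffs: dict[str, int]  # per-alternative edit distance (best window)
    genome_unique: bool

    @property
    def min_diff(self) -> int:
        return min(self.diffs.values()) if self.diffs else 0

    @property
    def spans_indel(self) -> bool:
        return any(e.startswith(("DEL", "INS")) for e in self.events)


def _event_id(kind: str, size: int, b_pos: int) -> str:
    return f"{kind}{size}@{b_pos}" if kind != "SNV" else f"SNV@{b_pos}"


def _count_exact_occurrences(pattern: str, sequences) -> int:
    """Exact occurrences of pattern or its reverse complement."""
    rc = _dna.revcomp(pattern)
    total = 0
    for seq in sequences:
        total += seq.count(pattern)
        if rc != pattern:
            total += seq.count(rc)
    return total


def design_diagnostic_kmers(
    target: str,
    alternatives: dict[str, str],
    k: int = 24,
    min_diff: int = 2,
    n_per_target: int = 4,
    reference: dict[str, str] | None = None,
    target_id: str = "target",
) -> list[DiagnosticKmer]:
    """Design up to ``n_per_target`` diagnostic k-mers on the target.

    Candidate windows span at least one indel junction (relative to the
    first alternative) or at least two linked SNVs.  A candidate survives
    when its edit distance to the best-matching window of EVERY
    alternative (computed by infix alignment) is >= ``min_diff``, it
    occurs exactly once in the target, and — when a reference is supplied
    — nowhere else in the genome.  Selection greedily covers distinct
    diagnostic events, indel-spanning candidates first (largest indel
    first), then fills remaining slots by decreasing difference count.
    """
    if not alternatives:
        raise ValueError("need at least one alternative sequence")
    primary = next(iter(alternatives.values()))
    aln = align_paralogs(primary, target)
    events = []  # (id, kind, b_lo, b_hi) footprint on target, half-open
    for _, v in aln.variants.iterrows():
        if v["kind"] == "SNV":
            events.append((_event_id("SNV", 1, int(v["b_start"])), "SNV",
                           int(v["b_start"]), int(v["b_end"])))
        elif v["kind"] == "DEL":  # absent from target: junction point
            size = int(v["a_end"] - v["a_start"])
            jb = int(v["b_start"])
            events.append((_event_id("DEL", size, jb), "DEL", jb, jb))
        else:  # INS: run present in target
            size = int(v["b_end"] - v["b_start"])
            events.append(
                (_event_id("INS", size, int(v["b_start"])), "INS",
                 int(v["b_start"]), int(v["b_end"]))
            )
    if not events:
        warnings.warn("paralogs are identical; no diagnostic k-mer possible")
        return []

    candidates: list[DiagnosticKmer] = []
    seen_seq: set[str] = set()
    for w in range(0, len(target) - k + 1):
        lo, hi = w, w + k
        covered = []
        n_snv = 0
        for eid, kind, b_lo, b_hi in events:
            if kind in ("DEL",):
                # junction strictly inside: both flanks represented
                if lo < b_lo < hi:
                    covered.append(eid)
            elif kind == "INS":
                if b_lo < hi and b_hi > lo:
                    covered.append(eid)
            else:
                if lo <= b_lo < hi:
                    covered.append(eid)
                    n_snv += 1
        spans_indel = any(not e.startswith("SNV") for e in covered)
        if not spans_indel and n_snv < 2:
            continue
        seq = target[lo:hi]
        if seq in seen_seq:
            continue
        if _count_exact_occurrences(seq, [target]) != 1:
            continue
        diffs = {}
        ok = True
        for name, alt in alternatives.items():
            d = edlib.align(seq, alt, mode="HW", task="distance")["editDistance"]
            d_rc = edlib.align(_dna.revcomp(seq), alt, mode="HW", task="distance")[
                "editDistance"
            ]
            d = min(d, d_rc)
            diffs[name] = int(d)
            if d < min_diff:
                ok = False
                break
        if not ok:
            continue
        genome_unique = True
        if reference is not None:
            n_hits = _count_exact_occurrences(seq, reference.values())
            genome_unique = n_hits <= 1  # the target locus itself, at most
            if not genome_unique:
                continue
        seen_seq.add(seq)
        candidates.append(
            DiagnosticKmer(
                sequence=seq,
                target_id=target_id,
                start=lo,
                end=hi,
                events=tuple(covered),
                diffs=diffs,
                genome_unique=genome_unique,
            )
        )
    if not candidates:
        warnings.warn("no candidate window satisfies the diagnostic criteria")
        return []

    # greedy selection: cover distinct indel events (largest first), then
    # fill by decreasing difference count
    def _indel_size(eid: str) -> int:
        kind_size = eid.split("@")[0]
        return int("".join(ch for ch in kind_size if ch.isdigit()) or 0)

    indel_events = sorted(
        {e for c in candidates for e in c.events if not e.startswith("SNV")},
        key=_indel_size,
        reverse=True,
    )
    selected: list[DiagnosticKmer] = []
    chosen_seqs: set[str] = set()
    for eid in indel_events:
        if len(selected) >= n_per_target:
            break
        pool = [
            c
            for c in candidates
            if eid in c.events and c.sequence not in chosen_seqs
        ]
        if not pool:
            continue
        best = max(pool, key=lambda c: (c.min_diff, len(c.events)))
        selected.append(best)
        chosen_seqs.add(best.sequence)
    rest = sorted(
        (c for c in candidates if c.sequence not in chosen_seqs),
        key=lambda c: (c.min_diff, len(c.events)),
        reverse=True,
    )
    for c in rest:
        if len(selected) >= n_per_target:
            break
        selected.append(c)
        chosen_seqs.add(c.sequence)
    return selected


def kmer_panel_table(kmers: list[DiagnosticKmer]) -> pd.DataFrame:
    rows = [
        (
            km.sequence,
            km.target_id,
            km.start,
            km.end,
            ";".join(km.events),
            km.min_diff,
            ";".join(f"{k}:{v}" for k, v in km.diffs.items()),
            km.genome_unique,
        )
        for km in kmers
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "kmer",
            "target",
            "start",
            "end",
            "events",
            "min_diff",
            "diffs",
            "genome_unique",
        ],
    )


# ---------------------------------------------------------------------------
# screening


@dataclass
class ScreenResult:
    """Outcome of screening one library for a diagnostic k-mer panel."""

    library_id: str
    counts: dict[str, int]
    positive: bool
    hit_read_indices: list[int] = field(default_factory=list)


def _scan_fastq(path, patterns: list[str]) -> tuple[dict[str, int], set[int]]:
    """Count canonical exact occurrences of each pattern; return counts and
    the set of 0-based read indices containing any pattern."""
    import pysam

    pats = []
    for p in patterns:
        rc = _dna.revcomp(p)
        pats.append((p, rc if rc != p else None))
    counts = {p: 0 for p in patterns}
    hits: set[int] = set()
    chunk: list[str] = []
    offsets: list[int] = []
    base_index = 0

    def _flush():
        nonlocal base_index
        if not chunk:
            return
        joined = "\n".join(chunk)
        bounds = np.cumsum([len(c) + 1 for c in chunk])
        for (p, rc), key in zip(pats, patterns):
            for pat in filter(None, (p, rc)):
                start = joined.find(pat)
                while start != -1:
                    counts[key] += 1
                    hits.add(base_index + int(np.searchsorted(bounds, start, "right")))
                    start = joined.find(pat, start + 1)
        base_index += len(chunk)
        chunk.clear()

    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            chunk.append(entry.sequence)
            if len(chunk) >= 100_000:
                _flush()
    _flush()
    return counts, hits


def screen_library(
    fastq_paths: list,
    kmers: list[DiagnosticKmer] | list[str],
    library_id: str = "",
    detect_min: int = 1,
) -> ScreenResult:
    """Exact canonical counts of diagnostic k-mers in a library.

    ``fastq_paths`` may hold one (single-end) or two (paired) files.
    Positive iff any k-mer count >= ``detect_min``.  Empty libraries are
    negative with zero counts.
    """
    patterns = [k.sequence if isinstance(k, DiagnosticKmer) else k for k in kmers]
    total = {p: 0 for p in patterns}
    hit_reads: list[int] = []
    for mate_no, path in enumerate(fastq_paths):
        counts, hits = _scan_fastq(path, patterns)
        for p, c in counts.items():
            total[p] += c
        hit_reads.extend(sorted(hits))
    positive = any(c >= detect_min for c in total.values())
    return ScreenResult(
        library_id=library_id or str(fastq_paths[0]),
        counts=total,
        positive=positive,
        hit_read_indices=sorted(set(hit_reads)),
    )


# ---------------------------------------------------------------------------
# extraction and reconstruction


@dataclass
class Fragment:
    """A reconstructed (or unmerged) transcript fragment from a read pair."""

    pair_id: str
    sequence: str
    merged: bool
    target_span: tuple[int, int] | None
    events_covered: tuple[str, ...]
    n_linked_events: int
    validated: bool
    downstream_of_stop: bool


def _merge_pair(r1: str, r2: str, min_overlap: int = 10) -> str | None:
    """Merge mates by maximal exact suffix/prefix overlap (mate 2 given as
    sequenced; it is reverse-complemented here)."""
    rc2 = _dna.revcomp(r2)
    max_o = min(len(r1), len(rc2))
    for o in range(max_o, min_overlap - 1, -1):
        if r1[-o:] == rc2[:o]:
            return r1 + rc2[o:]
    return None


def extract_and_reconstruct(
    r1_path,
    r2_path,
    kmers: list[DiagnosticKmer],
    target: str,
    min_overlap: int = 10,
    stop_target_pos: int | None = None,
    max_edit_frac: float = 0.1,
) -> list[Fragment]:
    """Extract read pairs containing any diagnostic k-mer and reconstruct
    transcript fragments with linked-variant validation.

    Pairs where either mate contains a diagnostic k-mer (canonical match)
    are extracted; overlapping mates are merged by maximal exact overlap
    (>= ``min_overlap`` bp), otherwise both mates are kept as separate
    fragments.  Each fragment is located on the target by infix alignment;
    the linked diagnostic variant count is the number of distinct
    diagnostic events whose target footprint lies inside the aligned span.
    Fragments covering >= 2 events are marked validated.  When
    ``stop_target_pos`` is given, fragments extending beyond it are
    flagged (transcription downstream of the truncation).
    """
    import pysam

    patterns = [k.sequence for k in kmers]
    _, hits1 = _scan_fastq(r1_path, patterns)
    _, hits2 = _scan_fastq(r2_path, patterns)
    wanted = hits1 | hits2
    if not wanted:
        return []
    pairs: dict[int, list] = {}
    for path, slot in ((r1_path, 0), (r2_path, 1)):
        with pysam.FastxFile(str(path)) as fh:
            for i, entry in enumerate(fh):
                if i in wanted:
                    pairs.setdefault(i, [None, None, entry.name])[slot] = entry.sequence

    footprints: dict[str, tuple[int, int]] = {}
    for km in kmers:
        for eid in km.events:
            if eid not in footprints:
                footprints[eid] = _event_footprint(eid)

    out: list[Fragment] = []
    for i in sorted(pairs):
        r1, r2, name = pairs[i]
        fragments = []
        merged = None
        if r1 and r2:
            merged = _merge_pair(r1, r2, min_overlap)
        if merged is not None:
            fragments.append((merged, True))
        else:
            if r1:
                fragments.append((r1, False))
            if r2:
                fragments.append((_dna.revcomp(r2), False))
        for seq, was_merged in fragments:
            span = _locate(seq, target, max_edit_frac)
            covered = []
            downstream = False
            if span is not None:
                lo, hi = span
                for eid, (b_lo, b_hi) in footprints.items():
                    if (b_lo == b_hi and lo < b_lo < hi) or (
                        b_lo < b_hi and b_lo >= lo and b_hi <= hi
                    ):
                        covered.append(eid)
                if stop_target_pos is not None and hi > stop_target_pos + 3:
                    downstream = True
            n_linked = len(set(covered))
            out.append(
                Fragment(
                    pair_id=name,
                    sequence=seq,
                    merged=was_merged,
                    target_span=span,
                    events_covered=tuple(sorted(set(covered))),
                    n_linked_events=n_linked,
                    validated=n_linked >= 2,
                    downstream_of_stop=downstream,
                )
            )
    return out


def _event_footprint(eid: str) -> tuple[int, int]:
    kind_size, pos = eid.split("@")
    pos = int(pos)
    if kind_size.startswith("INS"):
        return pos, pos + int(kind_size[3:] or 0)
    if kind_size.startswith("DEL"):
        return pos, pos  # junction
    return pos, pos + 1


def _locate(seq: str, target: str, max_edit_frac: float) -> tuple[int, int] | None:
    best = None
    for q in (seq, _dna.revcomp(seq)):
        res = edlib.align(q, target, mode="HW", task="locations")
        d = res["editDistance"]
        if d < 0 or d > max_edit_frac * len(seq):
            continue
        if res["locations"]:
            lo, hi = res["locations"][0]
            cand = (d, (int(lo), int(hi) + 1))
            if best is None or cand[0] < best[0]:
                best = cand
    return best[1] if best else None
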