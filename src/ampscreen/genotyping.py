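"""Editing-outcome genotyping from merged amplicon reads.

A locus is an expected wild-type amplicon (primer to primer) carrying one to
three Cas9 cut sites. Each merged read is aligned to the amplicon, its indels
are extracted and left-aligned to a canonical placement, and the read is
classified into one outcome category:

- ``wildtype``: no indels, alignment flush with both amplicon ends
  (point mismatches are tolerated — sequencing errors and SNPs are not
  evidence of editing);
- ``deletion`` / ``insertion``: exactly one indel;
- ``spanning_deletion``: a single deletion whose interval covers two or more
  cut sites (the signature outcome of multi-guide RNPs);
- ``multiple_indels``: two or more indels, none spanning;
- ``malformed_layout``: alignment boundaries too far from every cut site
  (one boundary >40 bp or both >20 bp) — typically amplification of a
  partially complementary off-target fragment rather than a real editing
  outcome;
- ``unaligned``: no acceptable alignment to the amplicon.

Counts per outcome are then corrected for amplicon-length observation bias
and summarised as a percent editing efficiency over on-target reads.

Coordinates are 0-based and half-open; cut site ``i`` denotes the blunt cut
between reference positions ``i-1`` and ``i``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd
from Bio import Align

from .errors import InputError
from .size_bias import BiasModel, correct_count

MULTI_GUIDE_WINDOW_BP = 200  # max span of tiled cut sites in a multi-guide design

# Alignment scoring: conventional amplicon-genotyping parameters. End gaps on
# the read are free (the read may start/end inside the reference); end gaps on
# the reference are penalized like internal gaps.
MATCH_SCORE = 1
MISMATCH_SCORE = -1
GAP_OPEN_SCORE = -5   # score of the first gapped position
GAP_EXTEND_SCORE = -1  # each additional gapped position
# aligned=False below 0.6 * read length; judged on the alignment score with
# internal deletion penalties added back, so that the large deletions Cas9
# is expected to produce never disqualify a read
SCORE_FLOOR_FRACTION = 0.6

_VALID_READ = set("ACGTN")
_VALID_REF = set("ACGT")


class OutcomeCategory(str, Enum):
    WILDTYPE = "wildtype"
    DELETION = "deletion"
    INSERTION = "insertion"
    MULTIPLE_INDELS = "multiple_indels"
    SPANNING_DELETION = "spanning_deletion"
    MALFORMED_LAYOUT = "malformed_layout"
    UNALIGNED = "unaligned"

    def __str__(self) -> str:  # plain value in TSV output
        return self.value


#: Categories counted in the on-target denominator of editing efficiency.
ON_TARGET_CATEGORIES = frozenset({
    OutcomeCategory.WILDTYPE,
    OutcomeCategory.DELETION,
    OutcomeCategory.INSERTION,
    OutcomeCategory.MULTIPLE_INDELS,
    OutcomeCategory.SPANNING_DELETION,
})


@dataclass(frozen=True)
class LocusSpec:
    """An amplicon reference with its Cas9 cut sites.

    ``cut_sites`` are 0-based offsets into ``reference_seq``; site ``i`` is
    the blunt cut between positions ``i-1`` and ``i``. Multi-guide designs
    tile 2-3 cut sites within a 200 bp window.
    """

    name: str
    reference_seq: str
    cut_sites: tuple[int, ...]
    sgrna_seqs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.reference_seq:
            raise InputError("reference sequence is empty")
        if set(self.reference_seq) - _VALID_REF:
            raise InputError(f"locus {self.name!r}: reference contains "
                             "non-ACGT characters")
        sites = tuple(int(c) for c in self.cut_sites)
        if not 1 <= len(sites) <= 3:
            raise InputError(f"locus {self.name!r}: need 1-3 cut sites")
        if list(sites) != sorted(set(sites)):
            raise InputError(f"locus {self.name!r}: cut sites must be "
                             "sorted, distinct")
        if sites[0] <= 0 or sites[-1] >= len(self.reference_seq):
            raise InputError(f"locus {self.name!r}: cut sites must lie "
                             "strictly inside the reference")
        if len(sites) > 1 and sites[-1] - sites[0] > MULTI_GUIDE_WINDOW_BP:
            raise InputError(f"locus {self.name!r}: cut sites span "
                             f"{sites[-1] - sites[0]} bp "
                             f"(> {MULTI_GUIDE_WINDOW_BP} bp window)")
        object.__setattr__(self, "cut_sites", sites)

    @property
    def amplicon_length_wt(self) -> int:
        """Length of the wild-type amplicon in bp."""
        return len(self.reference_seq)


@dataclass(frozen=True)
class Indel:
    """One indel in reference coordinates, leftmost-canonical.

    For deletions, ``ref_start`` is the first deleted reference position;
    for insertions, the inserted sequence sits before ``ref_start``.
    """

    kind: str  # "deletion" | "insertion"
    ref_start: int
    length: int
    inserted_seq: str = ""

    def covers_cut_site(self, cut: int) -> bool:
        """Whether a deletion interval touches or spans the cut point."""
        return (self.kind == "deletion"
                and self.ref_start <= cut <= self.ref_start + self.length)


@dataclass(frozen=True)
class ReadAlignment:
    """Alignment of one merged read against a locus reference."""

    read_length: int
    indels: tuple[Indel, ...]
    left_boundary_offset: int   # bp of reference left of the first aligned base
    right_boundary_offset: int  # bp of reference right of the last aligned base
    aligned: bool
    score: float = 0.0


@dataclass(frozen=True)
class OutcomeCall:
    """Classification of one read: category, canonical outcome key, length."""

    category: OutcomeCategory
    outcome_key: str
    length: int  # bp of the implied amplicon (the read length)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN_SCORE
    aligner.extend_gap_score = GAP_EXTEND_SCORE
    # free end gaps on the read only: the read may not cover the reference
    # ends, but read overhang beyond the reference is penalized
    aligner.open_left_deletion_score = 0
    aligner.extend_left_deletion_score = 0
    aligner.open_right_deletion_score = 0
    aligner.extend_right_deletion_score = 0
    return aligner


_ALIGNER = _make_aligner()


def left_align_indels(ref: str, indels: list[Indel],
                      left_bound: int = 0) -> tuple[Indel, ...]:
    """Shift indels to their leftmost equivalent placement.

    A deletion shifts left while the base entering the deleted window from
    the left equals the base leaving it on the right; an insertion rotates
    its sequence while the reference base to its left equals its last base.
    Shifts stop at ``left_bound`` or at the previous indel. This makes
    identical biological outcomes share one canonical key regardless of
    which optimal alignment the aligner happened to report.
    """
    out: list[Indel] = []
    prev_end = left_bound
    for ind in sorted(indels, key=lambda i: i.ref_start):
        if ind.kind == "deletion":
            s, ln = ind.ref_start, ind.length
            while s > prev_end and ref[s - 1] == ref[s + ln - 1]:
                s -= 1
            out.append(Indel("deletion", s, ln))
            prev_end = s + ln
        else:
            p, seq = ind.ref_start, ind.inserted_seq
            while p > prev_end and ref[p - 1] == seq[-1]:
                seq = ref[p - 1] + seq[:-1]
                p -= 1
            out.append(Indel("insertion", p, ind.length, seq))
            prev_end = p
    return tuple(out)


def _make_anchored_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN_SCORE
    aligner.extend_gap_score = GAP_EXTEND_SCORE
    return aligner


_ANCHORED_ALIGNER = _make_anchored_aligner()


def _extract(alignment, ref: str, read_seq: str
             ) -> tuple[list[Indel], int, int, float]:
    """Indels, boundary offsets and internal-deletion penalty of an alignment."""
    target_blocks, query_blocks = alignment.aligned
    left_off = int(target_blocks[0][0])
    right_off = len(ref) - int(target_blocks[-1][1])

    indels: list[Indel] = []
    deletion_penalty = 0.0
    # read bases overhanging the aligned region are reported as insertions
    # at the alignment boundaries
    lead = int(query_blocks[0][0])
    if lead:
        indels.append(Indel("insertion", left_off, lead, read_seq[:lead]))
    trail = len(read_seq) - int(query_blocks[-1][1])
    if trail:
        indels.append(Indel("insertion", len(ref) - right_off, trail,
                            read_seq[len(read_seq) - trail:]))
    for k in range(len(target_blocks) - 1):
        t_gap = int(target_blocks[k + 1][0]) - int(target_blocks[k][1])
        q_gap = int(query_blocks[k + 1][0]) - int(query_blocks[k][1])
        pos = int(target_blocks[k][1])
        if t_gap > 0:
            indels.append(Indel("deletion", pos, t_gap))
            deletion_penalty += GAP_OPEN_SCORE + (t_gap - 1) * GAP_EXTEND_SCORE
        if q_gap > 0:
            ins = read_seq[int(query_blocks[k][1]):int(query_blocks[k + 1][0])]
            indels.append(Indel("insertion", pos + t_gap, q_gap, ins))
    return indels, left_off, right_off, deletion_penalty


def _end_gap_penalty(offset: int) -> float:
    if offset == 0:
        return 0.0
    return GAP_OPEN_SCORE + (offset - 1) * GAP_EXTEND_SCORE


def align_read(read_seq: str, locus: LocusSpec) -> ReadAlignment:
    """Align one merged read to the locus reference.

    Global alignment with free end gaps on the read (the read may begin or
    end inside the reference without penalty). Large deletions — the
    expected outcome of multi-guide designs — are affinely expensive, so
    the free-end optimum can instead misalign a flank against an unrelated
    reference region; whenever the free-end alignment is non-flush or
    low-quality, a fully anchored (both-ends-penalized) alignment is also
    computed, its end gaps are reinterpreted as boundary offsets, and the
    alignment explaining more of the read (score with internal deletion
    penalties forgiven) wins. Reads whose best quality is below
    ``SCORE_FLOOR_FRACTION * read_length`` are reported as unaligned.
    Indels are returned leftmost-canonical, sorted, non-overlapping.
    """
    if not read_seq:
        raise InputError("empty read")
    if set(read_seq) - _VALID_READ:
        raise InputError("read contains non-ACGTN characters")

    ref = locus.reference_seq
    aln1 = _ALIGNER.align(ref, read_seq)[0]
    indels, left_off, right_off, del_penalty = _extract(aln1, ref, read_seq)
    score = float(aln1.score)
    # quality forgives internal deletion penalties: a read whose bases all
    # match the reference is fully explained however much of the reference
    # was cut out between them
    quality = score - del_penalty

    floor = SCORE_FLOOR_FRACTION * len(read_seq)
    if quality < floor or left_off or right_off:
        aln2 = _ANCHORED_ALIGNER.align(ref, read_seq)[0]
        ind2, l2, r2, dp2 = _extract(aln2, ref, read_seq)
        # end gaps of the anchored alignment show up only in its score;
        # add them back so the two scores are on the free-end scale
        score2 = (float(aln2.score) - _end_gap_penalty(l2)
                  - _end_gap_penalty(r2))
        quality2 = score2 - dp2
        if quality2 > quality:
            indels, left_off, right_off = ind2, l2, r2
            score, quality = score2, quality2

    if quality < floor:
        return ReadAlignment(len(read_seq), (), 0, 0, aligned=False, score=score)

    canonical = left_align_indels(ref, indels, left_bound=left_off)
    return ReadAlignment(len(read_seq), canonical, left_off, right_off,
                         aligned=True, score=score)


def _boundary_distance(position: int, offset: int, cut_sites: tuple[int, ...]) -> int:
    """Distance of an alignment boundary to its nearest cut site.

    Boundaries flush with the reference ends (offset 0) count as distance 0:
    a full-length read carries no layout evidence at its ends.
    """
    if offset == 0:
        return 0
    return min(abs(position - c) for c in cut_sites)


def deletion_covers_cut(ind: Indel, ref: str, cut: int) -> bool:
    """Whether a (leftmost-placed) deletion spans a cut site under any of
    its shift-equivalent placements.

    A deletion in repetitive context has several equivalent placements; a
    cut site touched by any of them was plausibly the break that produced
    it, so coverage is judged over the whole equivalence range.
    """
    if ind.kind != "deletion":
        return False
    s_max = ind.ref_start
    while (s_max + ind.length < len(ref)
           and ref[s_max] == ref[s_max + ind.length]):
        s_max += 1
    return ind.ref_start <= cut <= s_max + ind.length


def _outcome_key(aln: ReadAlignment) -> str:
    parts = []
    if aln.left_boundary_offset:
        parts.append(f"trimL{aln.left_boundary_offset}")
    for ind in aln.indels:
        if ind.kind == "deletion":
            parts.append(f"del@{ind.ref_start}+{ind.length}")
        else:
            parts.append(f"ins@{ind.ref_start}+{ind.length}:{ind.inserted_seq}")
    if aln.right_boundary_offset:
        parts.append(f"trimR{aln.right_boundary_offset}")
    return ";".join(parts) if parts else "WT"


def classify_outcome(aln: ReadAlignment, locus: LocusSpec) -> OutcomeCall:
    """Assign one read alignment to an outcome category.

    The malformed-layout reclassification runs first: a read with one
    alignment boundary >40 bp from every cut site, or both boundaries
    >20 bp, is non-informative regardless of its indels. Partial reads
    (nonzero boundary offsets) without indels are likewise non-informative
    and never counted as wild type.
    """
    if not aln.aligned:
        return OutcomeCall(OutcomeCategory.UNALIGNED, "unaligned", aln.read_length)

    ref_len = locus.amplicon_length_wt
    d_left = _boundary_distance(aln.left_boundary_offset,
                                aln.left_boundary_offset, locus.cut_sites)
    d_right = _boundary_distance(ref_len - aln.right_boundary_offset,
                                 aln.right_boundary_offset, locus.cut_sites)
    key = _outcome_key(aln)
    if max(d_left, d_right) > 40 or min(d_left, d_right) > 20:
        return OutcomeCall(OutcomeCategory.MALFORMED_LAYOUT, key, aln.read_length)

    if not aln.indels:
        if aln.left_boundary_offset == 0 and aln.right_boundary_offset == 0:
            return OutcomeCall(OutcomeCategory.WILDTYPE, "WT", aln.read_length)
        # truncated but near-cut-site read without indels: no usable call
        return OutcomeCall(OutcomeCategory.MALFORMED_LAYOUT, key, aln.read_length)

    ref = locus.reference_seq
    n_spanned = [sum(deletion_covers_cut(ind, ref, c) for c in locus.cut_sites)
                 for ind in aln.indels]
    if any(ind.kind == "deletion" and n >= 2
           for ind, n in zip(aln.indels, n_spanned)):
        return OutcomeCall(OutcomeCategory.SPANNING_DELETION, key, aln.read_length)
    if len(aln.indels) == 1:
        cat = (OutcomeCategory.DELETION if aln.indels[0].kind == "deletion"
               else OutcomeCategory.INSERTION)
        return OutcomeCall(cat, key, aln.read_length)
    return OutcomeCall(OutcomeCategory.MULTIPLE_INDELS, key, aln.read_length)


@dataclass
class OutcomeTable:
    """Per-outcome tallies and the per-sample editing-efficiency summary.

    ``outcomes`` has one row per distinct outcome key with columns
    ``outcome_key, category, length, raw_count, corrected_count``.
    Efficiency is the corrected fraction of non-wild-type reads among
    on-target reads (malformed-layout and unaligned reads excluded from the
    denominator by default); samples are flagged usable when they carry
    more than 100 corrected on-target reads.
    """

    outcomes: pd.DataFrame
    category_totals: pd.DataFrame  # category, raw_count, corrected_count
    on_target_total_corrected: float
    editing_efficiency_pct: float
    passes_filter: bool

    READ_FILTER_MIN_CORRECTED = 100.0


def tabulate_outcomes(calls: list[OutcomeCall], locus: LocusSpec,
                      bias: BiasModel,
                      include_malformed_in_denominator: bool = False
                      ) -> OutcomeTable:
    """Aggregate per-read calls into size-corrected outcome counts."""
    cols = ["outcome_key", "category", "length", "raw_count", "corrected_count"]
    if not calls:
        empty = pd.DataFrame(columns=cols)
        totals = pd.DataFrame(columns=["category", "raw_count", "corrected_count"])
        return OutcomeTable(empty, totals, 0.0, float("nan"), False)

    counter: Counter[tuple[str, OutcomeCategory, int]] = Counter()
    for call in calls:
        counter[(call.outcome_key, call.category, call.length)] += 1

    rows = []
    l_wt = locus.amplicon_length_wt
    for (key, category, length), raw in sorted(counter.items(),
                                               key=lambda kv: -kv[1]):
        corrected = correct_count(raw, l_wt, length, bias)
        rows.append((key, category.value, length, raw, corrected))
    outcomes = pd.DataFrame(rows, columns=cols)

    totals = (outcomes.groupby("category", as_index=False)
              [["raw_count", "corrected_count"]].sum())

    denom_categories = {c.value for c in ON_TARGET_CATEGORIES}
    if include_malformed_in_denominator:
        denom_categories.add(OutcomeCategory.MALFORMED_LAYOUT.value)
    on_target = outcomes[outcomes["category"].isin(denom_categories)]
    on_target_corr = float(on_target["corrected_count"].sum())
    wt_corr = float(on_target.loc[
        on_target["category"] == OutcomeCategory.WILDTYPE.value,
        "corrected_count"].sum())
    if on_target_corr > 0:
        efficiency = 100.0 * (on_target_corr - wt_corr) / on_target_corr
    else:
        efficiency = float("nan")
    passes = on_target_corr > OutcomeTable.READ_FILTER_MIN_CORRECTED
    return OutcomeTable(outcomes, totals, on_target_corr, efficiency, passes)
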