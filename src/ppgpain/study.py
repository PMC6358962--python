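"""Reference study-design constants and arithmetic.

The reference clinical cohort consists of 100 post-surgical patients, each
recorded for 14 minutes before and immediately after surgery and interviewed
with the numeric rating scale (NRS, 0 = no pain to 10 = worst pain). NRS >= 4
(moderate or severe pain) marks pain requiring active treatment. The 2-class
protocol (no pain N vs pain-requiring-treatment P) keeps subjects reporting
moderate/severe postoperative pain; the 4-class protocol (none / mild /
moderate / severe) keeps every subject reporting any pain.

These printed study facts are encoded here so that selection counts, split
sizes and window arithmetic are computable without the (undeposited) clinical
recordings.
"""

from __future__ import annotations

__all__ = [
    "NRS_POSTOP_COUNTS",
    "nrs_to_two_class",
    "nrs_to_four_class",
    "eligible_subject_count",
    "windows_per_record",
    "rows_for_subjects",
    "fold_subject_counts",
    "REFERENCE_SCREENED_OUT_TWO_CLASS",
]

#: Postoperative NRS distribution of the reference cohort (score -> subjects).
NRS_POSTOP_COUNTS: dict[int, int] = {
    0: 7, 1: 2, 2: 4, 3: 9, 4: 10, 5: 20, 6: 7, 7: 17, 8: 17, 9: 5, 10: 2,
}

#: Features that failed the paired two-class screening on the reference cohort.
REFERENCE_SCREENED_OUT_TWO_CLASS = ("rmssd", "nn50")


def nrs_to_two_class(nrs: int) -> str:
    """Map an NRS score to N (no pain) / P (pain requiring active treatment)."""
    if not 0 <= nrs <= 10:
        raise ValueError(f"NRS score must lie in [0, 10], got {nrs}")
    return "P" if nrs >= 4 else "N"


def nrs_to_four_class(nrs: int) -> str:
    """Map an NRS score to none / mild / moderate / severe pain status."""
    if not 0 <= nrs <= 10:
        raise ValueError(f"NRS score must lie in [0, 10], got {nrs}")
    if nrs == 0:
        return "none"
    if nrs <= 3:
        return "mild"
    if nrs <= 6:
        return "moderate"
    return "severe"


def eligible_subject_count(mode: str = "two_class") -> int:
    """Number of reference-cohort subjects entering the given protocol.

    ``two_class`` keeps moderate+severe reporters (NRS >= 4), ``four_class``
    keeps everyone reporting pain (NRS >= 1), ``all`` returns the cohort size.
    """
    if mode == "two_class":
        return sum(n for s, n in NRS_POSTOP_COUNTS.items() if s >= 4)
    if mode == "four_class":
        return sum(n for s, n in NRS_POSTOP_COUNTS.items() if s >= 1)
    if mode == "all":
        return sum(NRS_POSTOP_COUNTS.values())
    raise ValueError(f"unknown mode {mode!r}")


def windows_per_record(duration_s: float = 840.0, window_s: float = 300.0,
                       step_s: float = 60.0) -> int:
    """Number of sliding feature windows a record of given duration yields."""
    if duration_s < window_s:
        return 0
    return int((duration_s - window_s) // step_s) + 1


def rows_for_subjects(n_subjects: int, records_per_subject: int = 2,
                      windows: int = 10) -> int:
    """Feature-matrix rows contributed by ``n_subjects`` paired recordings."""
    return n_subjects * records_per_subject * windows


def fold_subject_counts(n_subjects: int, k: int) -> tuple[int, int, int]:
    """(train, validation, test) subject counts per fold.

    Each fold holds one of ``k`` near-equal subject groups out for testing and
    another for validation; the remainder trains. For 78 subjects and k=6 this
    gives 52/13/13.
    """
    if k < 3:
        raise ValueError("need k >= 3 to carve out train/validation/test roles")
    per_group = n_subjects // k
    return n_subjects - 2 * per_group, per_group, per_group
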