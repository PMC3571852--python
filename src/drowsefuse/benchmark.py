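"""Reference awake/drowsy confusion counts from a ten-subject simulator study.

Per-subject sample counts (awake total, drowsy total, awake true, drowsy
true) used to validate the confusion-table percentage arithmetic.  The
source table of subject J's drowsy column prints 96 %/4 %, which is
arithmetically inconsistent with its own counts (165/173 = 95.4 %); the
printed percentages below therefore carry the two entries as published,
and callers comparing against recomputed values should expect 95/5 there.
"""

from .pipeline import ConfusionTable, summarize

__all__ = ["SUBJECT_COUNTS", "PRINTED_PERCENTAGES", "subject_tables", "total_table"]

#: subject -> (aw_total, dw_total, aw_true, dw_true)
SUBJECT_COUNTS = {
    "A": (126, 142, 118, 133),
    "B": (182, 155, 176, 146),
    "C": (146, 137, 141, 132),
    "D": (167, 166, 161, 164),
    "E": (181, 171, 179, 165),
    "F": (157, 166, 150, 164),
    "G": (186, 175, 178, 174),
    "H": (153, 149, 148, 145),
    "I": (163, 181, 155, 176),
    "J": (144, 173, 135, 165),
}

#: subject -> (aw_true%, dw_true%, aw_false%, dw_false%) as published
PRINTED_PERCENTAGES = {
    "A": (94, 94, 6, 6),
    "B": (97, 94, 3, 6),
    "C": (97, 96, 3, 4),
    "D": (96, 99, 4, 1),
    "E": (99, 96, 1, 4),
    "F": (96, 99, 4, 1),
    "G": (96, 99, 4, 1),
    "H": (97, 97, 3, 3),
    "I": (95, 97, 5, 3),
    "J": (94, 96, 6, 4),  # drowsy pair inconsistent with the counts; see module docstring
    "Total": (96, 97, 4, 3),
}


def subject_tables() -> dict[str, ConfusionTable]:
    return {
        name: ConfusionTable(aw_total=aw, dw_total=dw, aw_true=awt, dw_true=dwt)
        for name, (aw, dw, awt, dwt) in SUBJECT_COUNTS.items()
    }


def total_table() -> ConfusionTable:
    return summarize(list(subject_tables().values()))
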