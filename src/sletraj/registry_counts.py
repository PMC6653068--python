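"""Published per-subgroup characteristic counts from the Australian Lupus
Registry SLE cohort (110 patients, 843 visits).

The time-warped clustering of the registry's Group 1 split it into Subgroup
1A (n = 69) and Subgroup 1B (n = 32). For each baseline characteristic and
adverse outcome the counts below record how many patients in each subgroup
carried the flag; they serve as worked-example inputs for the 2x2
association analysis (Subgroup 1B is the exposed group).
"""

from .association import ContingencyTable2x2

N_1A = 69
N_1B = 32

#: characteristic -> (count in 1A of 69, count in 1B of 32)
SUBGROUP_COUNTS: dict[str, tuple[int, int]] = {
    "female": (55, 28),
    "male": (14, 4),
    "ethnicity_caucasian": (39, 12),
    "ethnicity_asian": (28, 18),
    "ethnicity_other": (2, 2),
    "diagnosis_age_lt18": (5, 6),
    "diagnosis_age_18_to_45": (49, 21),
    "diagnosis_age_ge45": (15, 5),
    "duration_lt10y": (24, 12),
    "duration_ge10y": (45, 20),
    "neurological": (2, 4),
    "musculoskeletal": (5, 12),
    "renal": (3, 7),
    "mucocutaneous": (10, 21),
    "serositis": (0, 2),
    "immunological": (13, 28),
    "hematological": (3, 4),
    "sfi_flare": (45, 28),
    "slicc_sdi_ge1": (34, 23),
    "sledai_gt4": (44, 29),
    "ams_first_quartile": (7, 19),
    "prednisolone": (51, 32),
    "prednisolone_gt7_5": (39, 30),
    "hydroxychloroquine": (66, 31),
    "immunosuppressants": (46, 32),
    "biologics": (1, 6),
}

#: organ-involvement, adverse-outcome and medication rows with a finite
#: published odds ratio that distinguished the subgroups, in table order
#: (prednisolone and immunosuppressants are all-of-1B degenerate rows)
HIGHLIGHTED_ROWS: tuple[str, ...] = (
    "neurological",
    "musculoskeletal",
    "renal",
    "mucocutaneous",
    "immunological",
    "sfi_flare",
    "slicc_sdi_ge1",
    "sledai_gt4",
    "ams_first_quartile",
    "prednisolone_gt7_5",
    "biologics",
)


def table_for(characteristic: str) -> ContingencyTable2x2:
    """2x2 table (1B exposed vs 1A unexposed) for a published characteristic."""
    with_1a, with_1b = SUBGROUP_COUNTS[characteristic]
    return ContingencyTable2x2(
        a=with_1b, b=N_1B - with_1b, c=with_1a, d=N_1A - with_1a
    )
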