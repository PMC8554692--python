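"""Published two-group tumor-pattern counts for validation.

Case counts from the published analysis of the IARC germline TP53 data
set (release 20), comparing patients who met LFS genetic testing
criteria (or had any cancer before age 18) against patients who did
not. Group case totals: 2543 met (in 2319 patients) and 762 not-met
(in 678 patients). These counts serve as fixed reference inputs for the
contingency machinery; the underlying individual-level database is not
redistributed.

Two internal inconsistencies of the published table are known and left
as printed: the organ percentages there are consistent with a met-group
denominator of 2541 rather than the stated 2543, and the not-met
glioblastoma percentage is printed as 38.6 although 23/57 = 40.4. The
code here always recomputes percentages from counts.
"""

from __future__ import annotations

MET_TOTAL_CASES = 2543
NOT_MET_TOTAL_CASES = 762
MET_TOTAL_PATIENTS = 2319
NOT_MET_TOTAL_PATIENTS = 678

#: (label, met-group cases, not-met-group cases)
ORGAN_ROWS: list[tuple[str, int, int]] = [
    ("breast", 700, 292),
    ("soft_tissues", 303, 56),
    ("adrenal_gland", 166, 0),
    ("brain", 360, 57),
    ("bones", 279, 3),
    ("hematopoietic", 129, 43),
    ("lung", 79, 41),
    ("colon_rectum", 81, 36),
    ("ovary", 30, 24),
    ("liver", 27, 4),
    ("prostate", 33, 10),
    ("skin", 31, 27),
    ("stomach", 77, 24),
    ("kidney", 11, 11),
    ("pancreas", 19, 24),
    ("not_specified", 136, 59),
]

#: Soft-tissue sarcoma histology detail (subset with morphology known).
SOFT_TISSUE_ROWS: list[tuple[str, int, int]] = [
    ("fibrosarcoma", 13, 0),
    ("leiomyosarcoma", 41, 13),
    ("liposarcoma", 18, 9),
    ("rhabdomyosarcoma", 116, 6),
    ("malignant_fibrous_histiocytoma", 13, 2),
    ("sarcoma_other", 26, 4),
    ("sarcoma_nos", 76, 22),
]

#: Brain tumor histology detail; cancer_nos is tabulated within the
#: brain denominator in the published table.
BRAIN_ROWS: list[tuple[str, int, int]] = [
    ("astrocytoma", 43, 10),
    ("choroid_plexus_carcinoma", 46, 0),
    ("ependymoma", 5, 2),
    ("glioblastoma_glioma", 45, 23),
    ("medulloblastoma", 41, 1),
    ("pnet", 10, 1),
    ("brain_other", 17, 6),
    ("cancer_nos", 153, 14),
]

#: Brazilian p.R337H founder subgroup (excluded from the main analysis).
R337H_TOTAL_CARRIERS = 282
R337H_MET_CRITERIA = 193
R337H_MET_VIA_FAMILIAL_ACC = 141
R337H_NOT_MET_WITH_CANCER = 28
R337H_CANCER_FREE = 61
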