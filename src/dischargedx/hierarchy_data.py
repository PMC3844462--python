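"""Built-in ICD-9-CM chapter and block range tables.

Diagnosis chapters and blocks follow the standard ICD-9-CM tabular list
(numeric codes 001-999 plus the supplementary V classification).  Procedure
codes (Volume 3, two-digit roots) carry their own chapter table; Volume 3
publishes no block layer between the body-system ranges and the two-digit
roots, so each root doubles as its own block.
"""

from __future__ import annotations

# (start, end, label) over the integer value of the 3-digit root.
DIAGNOSIS_CHAPTERS = [
    (1, 139, "infectious and parasitic diseases"),
    (140, 239, "neoplasms"),
    (240, 279, "endocrine, nutritional, metabolic, immunity"),
    (280, 289, "blood and blood-forming organs"),
    (290, 319, "mental disorders"),
    (320, 389, "nervous system and sense organs"),
    (390, 459, "circulatory system"),
    (460, 519, "respiratory system"),
    (520, 579, "digestive system"),
    (580, 629, "genitourinary system"),
    (630, 679, "complications of pregnancy and childbirth"),
    (680, 709, "skin and subcutaneous tissue"),
    (710, 739, "musculoskeletal system and connective tissue"),
    (740, 759, "congenital anomalies"),
    (760, 779, "perinatal conditions"),
    (780, 799, "symptoms, signs, ill-defined conditions"),
    (800, 999, "injury and poisoning"),
]

DIAGNOSIS_BLOCKS = [
    (1, 9), (10, 18), (20, 27), (30, 41), (42, 42), (45, 49), (50, 59),
    (60, 66), (70, 79), (80, 88), (90, 99), (100, 104), (110, 118),
    (120, 129), (130, 136), (137, 139),
    (140, 149), (150, 159), (160, 165), (170, 176), (179, 189), (190, 199),
    (200, 208), (209, 209), (210, 229), (230, 234), (235, 238), (239, 239),
    (240, 246), (249, 259), (260, 269), (270, 279),
    (280, 289),
    (290, 294), (295, 299), (300, 316), (317, 319),
    (320, 327), (330, 337), (338, 338), (339, 339), (340, 349), (350, 359),
    (360, 379), (380, 389),
    (390, 392), (393, 398), (401, 405), (410, 414), (415, 417), (420, 429),
    (430, 438), (440, 449), (451, 459),
    (460, 466), (470, 478), (480, 488), (490, 496), (500, 508), (510, 519),
    (520, 529), (530, 539), (540, 543), (550, 553), (555, 558), (560, 569),
    (570, 579),
    (580, 589), (590, 599), (600, 608), (610, 612), (614, 616), (617, 629),
    (630, 639), (640, 649), (650, 659), (660, 669), (670, 677), (678, 679),
    (680, 686), (690, 698), (700, 709),
    (710, 719), (720, 724), (725, 729), (730, 739),
    (740, 759),
    (760, 763), (764, 779),
    (780, 789), (790, 796), (797, 799),
    (800, 804), (805, 809), (810, 819), (820, 829), (830, 839), (840, 848),
    (850, 854), (860, 869), (870, 879), (880, 887), (890, 897), (900, 904),
    (905, 909), (910, 919), (920, 924), (925, 929), (930, 939), (940, 949),
    (950, 957), (958, 959), (960, 979), (980, 989), (990, 995), (996, 999),
]

# Supplementary V classification: one chapter, blocks by root range.
V_CHAPTER = "supplementary classification (V)"
V_BLOCKS = [
    (1, 9), (10, 19), (20, 29), (30, 39), (40, 49), (50, 59), (60, 69),
    (70, 82), (83, 91),
]

# External-cause E classification (parsed but excluded by code filtering).
E_CHAPTER = "external causes of injury (E)"

# ICD-9 Volume 3 procedure body-system ranges over the 2-digit root.
PROCEDURE_CHAPTERS = [
    (0, 0, "procedures and interventions NEC"),
    (1, 5, "operations on the nervous system"),
    (6, 7, "operations on the endocrine system"),
    (8, 16, "operations on the eye"),
    (17, 17, "other miscellaneous procedures"),
    (18, 20, "operations on the ear"),
    (21, 29, "operations on the nose, mouth and pharynx"),
    (30, 34, "operations on the respiratory system"),
    (35, 39, "operations on the cardiovascular system"),
    (40, 41, "operations on the hemic and lymphatic system"),
    (42, 54, "operations on the digestive system"),
    (55, 59, "operations on the urinary system"),
    (60, 64, "operations on the male genital organs"),
    (65, 71, "operations on the female genital organs"),
    (72, 75, "obstetrical procedures"),
    (76, 84, "operations on the musculoskeletal system"),
    (85, 86, "operations on the integumentary system"),
    (87, 99, "miscellaneous diagnostic and therapeutic procedures"),
]
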