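"""Published worked-example data for a staged goat muscle miRNA study.

A published deep-sequencing study of goat *longissimus dorsi* across three
prenatal stages (E45, E60, E105) and one neonatal stage (B3) reported the
nineteen most abundant known miRNAs (>10,000 RPM overall) with per-stage
RPM values, their overall averages and percent of total expression. Those
printed values are reproduced here as a worked example for the summary
arithmetic: the overall average equals the unweighted mean of the four
stage means, and the percent column is each miRNA's share of total
retained known-miRNA expression.
"""

from __future__ import annotations

import pandas as pd

#: stage labels in temporal order
STAGES = ("E45", "E60", "E105", "B3")

#: most abundant known miRNAs (>10,000 RPM): per-stage RPM, overall
#: average RPM, percent of total RPM, as printed in the study's table
TOP19_ABUNDANCE = pd.DataFrame(
    [
        ("chi-miR-1", 6295.55, 46071.45, 57320.36, 189598.96, 74821.58, 10.59),
        ("chi-miR-206", 14431.74, 42889.82, 43362.45, 45839.08, 36630.77, 5.18),
        ("chi-miR-136-5p", 24987.69, 39717.23, 63624.06, 17124.32, 36363.32, 5.15),
        ("chi-miR-125b-5p", 75912.97, 27792.61, 22774.97, 18196.78, 36169.33, 5.12),
        ("chi-miR-199a-5p", 60496.56, 39203.87, 22301.77, 10368.77, 33092.74, 4.68),
        ("chi-miR-127-3p", 19427.97, 32673.96, 50650.07, 14755.67, 29376.92, 4.16),
        ("chi-miR-378-3p", 13468.09, 18796.43, 17111.45, 35972.47, 21337.11, 3.02),
        ("chi-miR-199a-3p", 32368.72, 20436.40, 14383.53, 8331.90, 18880.14, 2.67),
        ("chi-let-7f-5p", 8267.54, 25391.62, 19610.74, 21285.13, 18638.76, 2.64),
        ("chi-miR-381", 1163.04, 15798.25, 39639.43, 16014.21, 18153.73, 2.57),
        ("chi-let-7a-5p", 12391.40, 21288.32, 20529.56, 16818.11, 17756.85, 2.51),
        ("chi-miR-26a-5p", 11827.52, 15451.15, 14309.29, 23221.40, 16202.34, 2.29),
        ("chi-miR-424-5p", 9682.27, 16680.34, 24418.99, 11053.80, 15458.85, 2.19),
        ("chi-miR-542-3p", 17859.67, 18067.31, 15563.14, 4943.97, 14108.52, 2.00),
        ("chi-miR-21-5p", 9380.94, 17679.31, 17354.65, 9719.30, 13533.55, 1.92),
        ("chi-let-7i-5p", 12745.99, 18266.53, 12772.41, 5858.31, 12410.81, 1.76),
        ("chi-miR-101-3p", 10321.09, 11493.82, 10860.86, 16368.79, 12261.14, 1.74),
        ("chi-miR-99a-5p", 16573.32, 13034.98, 10945.55, 7581.35, 12033.80, 1.70),
        ("chi-miR-133a-3p", 3148.03, 6608.13, 8574.40, 25567.65, 10974.55, 1.55),
    ],
    columns=["mirna", "E45", "E60", "E105", "B3",
             "overall_average_rpm", "percent_of_total"],
).set_index("mirna")

#: headline study-wide counts reported alongside the table
STUDY_COUNTS = {
    "total_raw_reads": 110_614_744,
    "n_libraries": 8,
    "n_known_mirnas": 410,
    "n_over_10000_rpm": 19,
    "n_homologs": 752,
    "n_novel": 88,
    "n_de_known": 221,
}
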