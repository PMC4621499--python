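"""Bundled example data.

A per-vessel measurement table from one healthy adult during room-air
breathing: 10 branch arteries and 11 branch veins around the optic nerve
head, with pulse-averaged velocity, lumen diameter, reported volumetric flow
and hemoglobin oxygen saturation per vessel. Vessel labels encode quadrant
(I/N/S/T = inferior/nasal/superior/temporal) and ordering.

Note on the reported flow column: the values are systematically about 0.89x
of v * pi * d^2 / 4 recomputed from the velocity and diameter columns in the
same table (a lumen-vs-wall diameter or velocity-averaging convention of the
original instrument software). The flow column is therefore useful for
flow-weighted aggregation exactly as reported, but should not be used to
validate the continuity formula against the printed velocities/diameters.
"""

from __future__ import annotations

import io

import pandas as pd

_EXAMPLE_SUBJECT_TSV = """\
vessel_id	vessel_type	velocity_mm_s	diameter_um	flow_ul_min	sao2_percent
I2	A	19.48	111.6	10.23	93.7
I3	A	7.53	70.2	1.56	93.2
I5	A	10.26	79.1	2.71	93.5
N1	A	7.94	80.8	2.19	92.4
N3	A	13.45	79.7	3.60	91.9
S2	A	7.78	65.6	1.41	77.8
S4	A	10.70	91.1	3.74	91.2
T2	A	10.22	82.1	3.14	94.3
T5	A	9.38	83.3	2.74	92.6
T7	A	15.79	109.1	7.93	91.5
I1	V	12.83	135.7	9.96	62.7
I4	V	5.34	93.5	1.97	67.2
I6	V	5.69	107.2	2.76	55.5
N2	V	6.31	108.6	3.14	59.0
N4	V	7.02	109.5	3.55	71.44
S1	V	8.40	165.5	9.71	67.8
S3	V	4.64	103.1	2.08	65.6
T1	V	2.72	80.7	0.75	57.1
T3	V	1.96	55.0	0.88	63.4
T4	V	7.87	71.1	1.68	62.4
T6	V	7.53	95.9	2.92	59.2
"""


def example_subject() -> pd.DataFrame:
    """Per-vessel measurements of one healthy adult at room air."""
    return pd.read_csv(io.StringIO(_EXAMPLE_SUBJECT_TSV), sep="\t")
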