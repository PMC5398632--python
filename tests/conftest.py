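"""Shared fixtures: the bundled classroom/academy examples and their
published transformed values (probabilities, z-scores, month midpoints).

One printed probability in the published transformation table (September,
top level) is internally inconsistent: the frequencies give 72/470 =
0.1532 and the published z-score (1.0228) matches 0.1532, but the table
prints .1539.  The frozen array below carries the value consistent with
the counts and the z.
"""

import numpy as np
import pytest

from ttgrae import datasets, to_probit_points


@pytest.fixture(scope="session")
def speaking_table():
    return datasets.speaking_listening_ratings()


@pytest.fixture(scope="session")
def speaking_points(speaking_table):
    return to_probit_points(speaking_table)


@pytest.fixture(scope="session")
def academy_points():
    return datasets.academy_selection_points()


#: Published upper-tail probabilities, rows Sep..Aug, columns >=2..>=5.
TABLE2_P = np.array([
    [.9936, .9106, .5681, .1532],   # .1532, not the printed .1539 (see module docstring)
    [.9710, .8951, .5179, .1362],
    [.9873, .9112, .4947, .1395],
    [.9808, .8699, .4307, .0938],
    [.9802, .8484, .4791, .1099],
    [.9696, .8454, .4169, .0843],
    [.9749, .8562, .4110, .0913],
    [.9713, .8541, .4091, .0742],
    [.9610, .8257, .3463, .0688],
    [.9494, .8115, .3218, .0575],
    [.9453, .7687, .3433, .0821],
    [.9668, .8031, .2634, .0614],
])

#: Published z-scores for the same cells.
TABLE2_Z = np.array([
    [-2.4902, -1.3447, -.1715, 1.0228],
    [-1.8954, -1.2541, -.0448, 1.0977],
    [-2.2357, -1.3482, .0132, 1.0824],
    [-2.0708, -1.1261, .1746, 1.3176],
    [-2.0583, -1.0294, .0524, 1.2271],
    [-1.8743, -1.0170, .2099, 1.3767],
    [-1.9580, -1.0632, .2251, 1.3326],
    [-1.9001, -1.0540, .2299, 1.4455],
    [-1.7625, -.9373, .3952, 1.4847],
    [-1.6393, -.8834, .4626, 1.5764],
    [-1.6007, -.7344, .4035, 1.3912],
    [-1.8351, -.8526, .6328, 1.5433],
])

#: Published mid-month birthtimes, Sep..Aug, 365-day year.
TABLE2_T = np.array([
    .0411, .1247, .2082, .2918, .3767, .4575,
    .5384, .6219, .7055, .7890, .8726, .9575,
])
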