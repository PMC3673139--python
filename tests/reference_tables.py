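"""Reference confusion matrices used as worked examples.

Row/column order is A1..A7 (rows actual, columns predicted), 30 test
instances per class.  SOCCER_BASELINE and HOCKEY_BASELINE come from the
black-box linear-SVM configuration (db4, level 2, 5-s window);
HOCKEY_TUNED from the best swept hockey model (MLP, bior1.1, level 6,
7-s window).  Their macro F-measures are the published worked-example
values 62.7%, 65.9% and 0.823.
"""

import numpy as np

SOCCER_BASELINE = np.array([
    [30, 0, 0, 0, 0, 0, 0],
    [3, 27, 0, 0, 0, 0, 0],
    [0, 0, 30, 0, 0, 0, 0],
    [0, 0, 0, 30, 0, 0, 0],
    [0, 15, 3, 0, 7, 4, 1],
    [4, 4, 2, 0, 7, 8, 5],
    [3, 4, 4, 0, 7, 4, 8],
])

HOCKEY_BASELINE = np.array([
    [30, 0, 0, 0, 0, 0, 0],
    [3, 27, 0, 0, 0, 0, 0],
    [0, 0, 30, 0, 0, 0, 0],
    [0, 0, 0, 30, 0, 0, 0],
    [0, 6, 5, 0, 11, 1, 7],
    [0, 1, 0, 0, 16, 1, 12],
    [0, 0, 1, 0, 9, 3, 17],
])

HOCKEY_TUNED = np.array([
    [30, 0, 0, 0, 0, 0, 0],
    [1, 29, 0, 0, 0, 0, 0],
    [0, 0, 30, 0, 0, 0, 0],
    [0, 0, 0, 30, 0, 0, 0],
    [0, 0, 0, 0, 19, 7, 4],
    [0, 0, 0, 0, 7, 15, 8],
    [0, 0, 0, 0, 4, 6, 20],
])
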