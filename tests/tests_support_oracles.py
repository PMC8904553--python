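"""Independent brute-force oracles shared by the acceptance suite."""

import numpy as np


def exhaustive_maxima_scan(power):
    """Run-based exhaustive scan for strict local maxima.

    An interior run of equal values is a maximum iff both adjacent runs are
    strictly lower; its leftmost index is reported.  Independent of the
    implementation under test.
    """
    power = np.asarray(power, dtype=float)
    idx = []
    i = 0
    n = len(power)
    while i < n:
        j = i
        while j + 1 < n and power[j + 1] == power[i]:
            j += 1
        if i > 0 and j < n - 1 and power[i - 1] < power[i] and power[j + 1] < power[i]:
            idx.append(i)
        i = j + 1
    return idx
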