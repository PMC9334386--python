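"""Independent brute-force oracles used to cross-check the metric engine.

These deliberately share no code with eflow.metrics: extremes come from an
exhaustive scan over every window position, pulse statistics from a literal
run-length scanner, and Colwell's measures from the entropy formulas applied
directly to a hand-built contingency matrix.
"""

import numpy as np


def exhaustive_window_extreme(values_by_year, window, kind):
    """Mean over years of the min/max of every contiguous window mean."""
    extremes = []
    for vals in values_by_year:
        vals = np.asarray(vals, dtype=float)
        if len(vals) < window:
            continue
        means = [
            vals[i : i + window].mean() for i in range(len(vals) - window + 1)
        ]
        extremes.append(min(means) if kind == "min" else max(means))
    return float(np.mean(extremes))


def run_length_scan(mask):
    """(count, [lengths]) of maximal runs of True by a literal scan."""
    lengths, n = [], 0
    for v in mask:
        if v:
            n += 1
        else:
            if n:
                lengths.append(n)
            n = 0
    if n:
        lengths.append(n)
    return len(lengths), lengths


def pulse_count_oracle(values_by_year, threshold, direction):
    """Mean annual count of excursions beyond a threshold (strict)."""
    counts = []
    for vals in values_by_year:
        vals = np.asarray(vals, dtype=float)
        mask = vals < threshold if direction == "below" else vals > threshold
        c, _ = run_length_scan(mask)
        counts.append(c * 365.0 / len(vals))
    return float(np.mean(counts))


def pulse_duration_oracle(values_by_year, threshold, direction):
    """Mean over years of the median within-year pulse duration."""
    medians = []
    for vals in values_by_year:
        vals = np.asarray(vals, dtype=float)
        mask = vals < threshold if direction == "below" else vals > threshold
        _, lengths = run_length_scan(mask)
        if lengths:
            medians.append(float(np.median(lengths)))
    return float(np.mean(medians)) if medians else 0.0


def colwell_from_matrix(matrix, n_total_states):
    """(constancy, predictability) from a contingency matrix by the entropy
    definitions, natural log."""
    N = np.asarray(matrix, dtype=float)
    total = N.sum()

    def h(p):
        p = p[p > 0]
        return float(-(p * np.log(p)).sum())

    hx = h(N.sum(axis=0) / total)  # months
    hy = h(N.sum(axis=1) / total)  # states
    hxy = h(N.ravel() / total)
    logs = np.log(n_total_states)
    return 1.0 - hy / logs, 1.0 - (hxy - hx) / logs


def broken_stick_oracle(proportions):
    """Literal b_j sums and the leading-run count, written long-hand."""
    p = len(proportions)
    k = 0
    for j in range(1, p + 1):
        b_j = sum(1.0 / i for i in range(j, p + 1)) / p
        if proportions[j - 1] > b_j:
            k += 1
        else:
            break
    return k
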