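"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations: the genome
oracle matches character by character, and the frame-FRET oracle integrates
the state path on a fine time grid.
"""

from __future__ import annotations

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_count_one_strand(genome: str, query: str) -> int:
    """Character-by-character overlapping match count; N in the query matches
    anything, specified bases must match exactly (never an N in the genome)."""
    n, m = len(genome), len(query)
    count = 0
    for i in range(n - m + 1):
        ok = True
        for j in range(m):
            q = query[j]
            g = genome[i + j]
            if q == "N":
                continue
            if g != q:
                ok = False
                break
        if ok:
            count += 1
    return count


def naive_count(genome: str, query: str, both_strands: bool = True) -> int:
    total = naive_count_one_strand(genome, query)
    if both_strands:
        total += naive_count_one_strand(naive_revcomp(genome), query)
    return total


def frame_fret_oracle(path, fret_means, n_frames: int, dt: float, steps: int = 2000):
    """Occupancy-weighted mean FRET per frame by dense numerical sampling of
    the state path (live portion only)."""
    out = np.zeros(n_frames)
    for i in range(n_frames):
        t = (i + (np.arange(steps) + 0.5) / steps) * dt
        live = t < path.bleach_time
        if not live.any():
            out[i] = 0.0
            continue
        states = path.state_at(t[live])
        out[i] = np.sum(np.asarray(fret_means)[states]) / steps
    return out
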