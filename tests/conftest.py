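import itertools

import numpy as np
import pytest

from cocultrace.isotopes import ISOTOPES
from cocultrace.network import MSMSSpectrum


def brute_force_isotopologue_distribution(counts, max_shift, exclude_tracer=False):
    """Enumerate every isotope assignment of a small molecule.

    Independent oracle for the convolution-based natural-abundance
    distribution: iterates over the isotope choice of each individual atom
    and accumulates probability by nominal mass shift.  Only feasible for a
    handful of atoms.
    """
    atoms = []
    for el, n in counts.items():
        isos = ISOTOPES[el]
        if el == "C" and exclude_tracer:
            isos = [(isos[0][0], 1.0)]
        base = round(isos[0][0])
        choices = [(round(m) - base, ab) for m, ab in isos]
        atoms.extend([choices] * n)
    dist = np.zeros(max_shift + 1)
    for combo in itertools.product(*atoms):
        shift = sum(c[0] for c in combo)
        if shift <= max_shift:
            prob = 1.0
            for c in combo:
                prob *= c[1]
            dist[shift] += prob
    return dist


def exhaustive_modified_cosine(s1, s2, fragment_tol=0.5):
    """Optimal-assignment modified cosine by exhaustive matching enumeration.

    Considers every one-to-one subset matching of candidate peak pairs
    (direct or precursor-shifted) and returns the maximum achievable score.
    Exponential; use only for spectra with <= ~10 peaks.
    """
    w1 = np.sqrt(s1.intensity)
    w2 = np.sqrt(s2.intensity)
    n1, n2 = np.linalg.norm(w1), np.linalg.norm(w2)
    if n1 == 0 or n2 == 0 or len(s1) == 0 or len(s2) == 0:
        return 0.0, 0
    w1, w2 = w1 / n1, w2 / n2
    shift = s2.precursor_mz - s1.precursor_mz
    shifts = [0.0] if abs(shift) <= fragment_tol else [0.0, shift]
    pairs = [
        (w1[i] * w2[j], i, j)
        for i in range(len(s1))
        for j in range(len(s2))
        if any(abs(s1.mz[i] + sh - s2.mz[j]) <= fragment_tol for sh in shifts)
    ]

    best = [0.0, 0]

    def recurse(k, used1, used2, acc, cnt):
        if acc > best[0]:
            best[0], best[1] = acc, cnt
        if k == len(pairs):
            return
        recurse(k + 1, used1, used2, acc, cnt)
        p, i, j = pairs[k]
        if i not in used1 and j not in used2:
            recurse(k + 1, used1 | {i}, used2 | {j}, acc + p, cnt + 1)

    recurse(0, frozenset(), frozenset(), 0.0, 0)
    return min(best[0], 1.0), best[1]


def make_msms(spectrum_id, precursor, peaks, group=""):
    mz, inten = zip(*peaks)
    return MSMSSpectrum(
        spectrum_id=spectrum_id,
        precursor_mz=precursor,
        mz=np.array(mz, dtype=float),
        intensity=np.array(inten, dtype=float),
        group=group,
    )


@pytest.fixture(scope="session")
def study_scenario_small():
    """Packaged study scenario with a reduced background, for fast tests."""
    from cocultrace.simdata import study_scenario

    return study_scenario(seed=0, n_background=200)
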