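"""Brute-force per-base oracle for region-matrix construction.

Expands every sample's segments onto individual bases of a tiny genome,
independently of the region-set algorithm, and checks that the aligned
matrix reproduces the per-base value map exactly: same covered
footprint, and every (region, sample) entry equal to the per-base value
(fill value where uncovered) at every base of the region. Only usable
for genomes of a few kilobases.
"""

import numpy as np

from clonorigin.core import CnvSegment, CohortSample, GenomicInterval


def random_cohort(rng, genome_size=2000, n_samples=4, max_segments=6):
    """A random small single-chromosome cohort with per-sample disjoint segments."""
    cohort = []
    for i in range(n_samples):
        n_seg = int(rng.integers(0, max_segments + 1))
        cuts = np.sort(rng.choice(np.arange(1, genome_size + 1),
                                  size=min(2 * n_seg, genome_size), replace=False))
        segments = []
        for k in range(len(cuts) // 2):
            start, end = int(cuts[2 * k]), int(cuts[2 * k + 1] - 1)
            if end < start or rng.random() < 0.3:  # leave gaps between spans
                continue
            segments.append(
                CnvSegment(f"s{i}", GenomicInterval("chr1", start, end),
                           float(np.round(rng.normal(0, 1), 3)))
            )
        cohort.append(CohortSample(f"s{i}", "x", segments))
    return cohort


def per_base_maps(cohort, genome_size):
    """(samples x positions) per-base value array, NaN where uncovered.

    Row order follows the cohort; column 0 is unused (1-based positions).
    """
    stacked = np.full((len(cohort), genome_size + 1), np.nan)
    for row, sample in enumerate(cohort):
        for seg in sample.segments:
            stacked[row, seg.interval.start : seg.interval.end + 1] = seg.value
    return stacked


def count_mismatches(cohort, region_set, values, genome_size, fill_value=0.0):
    """Mismatched bases between the aligned matrix and the per-base map.

    Counts (base, sample) pairs where expanding the matrix disagrees
    with the raw segments, plus any base whose coverage status differs
    between the matrix footprint and the union of segment footprints.
    Zero means the matrix is exact.
    """
    stacked = per_base_maps(cohort, genome_size)
    expected = np.where(np.isnan(stacked), fill_value, stacked)
    covered = ~np.isnan(stacked).all(axis=0)

    expanded = np.full((len(cohort), genome_size + 1), np.nan)
    in_region = np.zeros(genome_size + 1, dtype=bool)
    for i, region in enumerate(region_set):
        sl = slice(region.start, region.end + 1)
        if in_region[sl].any():
            return genome_size  # overlapping regions: everything is wrong
        in_region[sl] = True
        expanded[:, sl] = values[i][:, None]

    mismatch = int(np.count_nonzero(in_region[1:] != covered[1:]))
    both = in_region & covered
    if both.any():
        mismatch += int(np.count_nonzero(expanded[:, both] != expected[:, both]))
    return mismatch
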