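"""Small shared helpers (chromosome ordering, RNG derivation)."""

from __future__ import annotations

import numpy as np

#: Natural karyotype order used everywhere a chromosome axis is sorted.
CHROM_ORDER = [str(i) for i in range(1, 23)] + ["X", "Y"]
_CHROM_RANK = {c: i for i, c in enumerate(CHROM_ORDER)}


def chrom_sort_key(label: str) -> tuple[int, str]:
    """Sort key placing 1..22 numerically before X and Y; unknown labels last."""
    lab = str(label).removeprefix("chr")
    return (_CHROM_RANK.get(lab, len(CHROM_ORDER)), lab)


def sort_chromosomes(labels) -> list[str]:
    return sorted(labels, key=chrom_sort_key)


def derived_rng(seed: int, *tags: int) -> np.random.Generator:
    """Independent generator stream for (seed, tags).

    Each generator in :mod:`pscqc.synthetic` uses a distinct tag so that the
    same configuration always reproduces the same output regardless of call
    order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]))
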