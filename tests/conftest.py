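"""Shared fixtures and independent oracles used across the suite."""

from __future__ import annotations

import math
from functools import lru_cache

import pandas as pd
import pytest
from Bio.Align import substitution_matrices

from arrayscan.io_formats import CodingRecord, ExpressionMatrix, translate_cds


def nw_oracle(
    a: str,
    b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> float:
    """Independent affine-gap global alignment score.

    Top-down recursion with an explicit end-state (diagonal / gap-in-a /
    gap-in-b), written separately from the package's iterative
    implementation. Gap of length k costs gap_open + (k - 1) * gap_extend.
    """
    sub = substitution_matrices.load(matrix)

    @lru_cache(maxsize=None)
    def rec(i: int, j: int, state: int) -> float:
        if i == 0 and j == 0:
            return 0.0 if state == 0 else -math.inf
        best = -math.inf
        if state == 0 and i > 0 and j > 0:
            s = sub[a[i - 1], b[j - 1]]
            best = s + max(rec(i - 1, j - 1, k) for k in range(3))
        elif state == 1 and j > 0:
            for prev in range(3):
                cost = gap_extend if prev == 1 else gap_open
                best = max(best, rec(i, j - 1, prev) - cost)
        elif state == 2 and i > 0:
            for prev in range(3):
                cost = gap_extend if prev == 2 else gap_open
                best = max(best, rec(i - 1, j, prev) - cost)
        return best

    return max(rec(len(a), len(b), k) for k in range(3))


def make_record(gene_id: str, cds: str) -> CodingRecord:
    return CodingRecord(gene_id, cds, translate_cds(cds))


@pytest.fixture
def six_tissue_matrix() -> ExpressionMatrix:
    frame = pd.DataFrame(
        {
            "skin": [0.2, 25.0, 40.0, 10.0],
            "stomach": [0.2, 5.0, 36.0, 9.0],
            "brain": [0.2, 5.0, 2.0, 11.0],
            "liver": [0.2, 5.0, 2.0, 10.0],
            "lung": [0.2, 5.0, 1.0, 10.0],
            "heart": [0.2, 5.0, 1.0, 9.5],
        },
        index=["g_nd", "g_tissue", "g_group", "g_other"],
    )
    return ExpressionMatrix(frame)
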