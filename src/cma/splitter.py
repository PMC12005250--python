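"""Random partition of a cohort into k equally sized sub-cohorts.

Splitting deliberately ignores relatedness: separating relatives across
sub-cohorts at random is what creates the between-cohort correlation the
corrected meta-analysis estimates and removes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CohortAssignment
from .errors import InvalidConfigError


def split_cohort(sample_ids, k: int, seed: int = 0) -> CohortAssignment:
    """Cut a seeded uniform permutation of the samples into k contiguous
    blocks; the first (n mod k) blocks get the extra sample."""
    sample_ids = np.asarray(list(sample_ids), dtype=object)
    n = len(sample_ids)
    if k < 1 or k > n:
        raise InvalidConfigError(f"split index k={k} outside 1..{n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    base, rem = divmod(n, k)
    labels = np.empty(n, dtype=int)
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        labels[perm[start:start + size]] = i + 1
        start += size
    assignment = pd.Series(labels, index=sample_ids, name="subcohort")
    return CohortAssignment(k=k, assignment=assignment, seed=seed)


def write_assignment(assignment: CohortAssignment, path) -> None:
    df = assignment.assignment.rename_axis("sample_id").reset_index()
    df.to_csv(path, sep="\t", index=False)


def read_assignment(path) -> CohortAssignment:
    df = pd.read_csv(path, sep="\t")
    series = pd.Series(df["subcohort"].to_numpy(int), index=df["sample_id"].astype(str))
    return CohortAssignment(k=int(series.max()), assignment=series, seed=-1)
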