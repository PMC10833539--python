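"""Shared exhaustive-enumeration harness for the constraint engine tests.

Admission results are packed into a bitmask: bit (policy_index * 2 +
sign_index) is set when the policy admits the sign for the triple.
"""

from __future__ import annotations

import itertools
from collections import Counter

from signet.constraints import (
    DeviationPolicy,
    NEGATIVE,
    POSITIVE,
    _admits,
    cell_status,
    cell_status_from_table,
)

POLICIES = [
    DeviationPolicy.delta0,
    DeviationPolicy.delta1,
    DeviationPolicy.delta1_regOFF,
    DeviationPolicy.delta2,
]
SIGNS = [POSITIVE, NEGATIVE]


def admission_bitmask(f, r, g, status_fn=cell_status) -> int:
    mask = 0
    for s_idx, sign in enumerate(SIGNS):
        statuses = [status_fn(fi, ri, gi, sign) for fi, ri, gi in zip(f, r, g)]
        for p_idx, policy in enumerate(POLICIES):
            if _admits(statuses, policy):
                mask |= 1 << (p_idx * 2 + s_idx)
    return mask


def exhaustive_bitmasks(n: int, status_fn=cell_status) -> dict[tuple, int]:
    levels = list(itertools.product((1, 2, 3, 4), repeat=n))
    return {
        (f, r, g): admission_bitmask(f, r, g, status_fn)
        for f in levels for r in levels for g in levels
    }


def admitted(mask: int, policy: DeviationPolicy, sign: str) -> bool:
    return bool(mask >> (POLICIES.index(policy) * 2 + SIGNS.index(sign)) & 1)
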