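"""Small shared helpers: errors, seeding, logging."""

from __future__ import annotations

import hashlib
import logging

logger = logging.getLogger("neurotax")


class ConfigurationError(ValueError):
    """Raised when a configuration object violates one of its invariants."""


def derive_seed(root_seed: int, name: str) -> int:
    """Derive a per-stage seed from a root seed and a stream name.

    All randomness in a pipeline run flows from one root seed through named
    substreams, so any stage can be re-run in isolation and reproduce its
    draws.  The result is kept below 2**31.
    """
    h = hashlib.sha256(f"{root_seed}:{name}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


def as_dense(x) -> "np.ndarray":  # noqa: F821
    import numpy as np
    import scipy.sparse as sp

    if sp.issparse(x):
        return np.asarray(x.todense())
    return np.asarray(x)
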