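"""Shared fixtures and oracles for the test suite."""

import numpy as np
import pytest

from multitomo.containers import allocate, leaves


def rand_fill(container, rng):
    """Fill every leaf of a container with standard-normal values."""
    for leaf in leaves(container):
        leaf.values[...] = rng.standard_normal(leaf.values.shape)
    return container


def flatten(container):
    return np.concatenate([l.values.ravel() for l in leaves(container)])


def container_size(geometry):
    probe = allocate(geometry, 0.0)
    return sum(l.values.size for l in leaves(probe))


def materialize(op):
    """Dense matrix of a linear operator, built column-by-column."""
    n = container_size(op.domain)
    cols = []
    for j in range(n):
        e = allocate(op.domain, 0.0)
        offset = 0
        for leaf in leaves(e):
            size = leaf.values.size
            if offset <= j < offset + size:
                leaf.values.reshape(-1)[j - offset] = 1.0
                break
            offset += size
        cols.append(flatten(op.direct(e)))
    return np.column_stack(cols)


def adjoint_mismatch(op, seed):
    """Relative adjoint-identity error on one random probe pair."""
    rng = np.random.default_rng(seed)
    x = rand_fill(allocate(op.domain, 0.0), rng)
    y = rand_fill(allocate(op.range, 0.0), rng)
    lhs = op.direct(x).inner(y)
    rhs = x.inner(op.adjoint(y))
    return abs(lhs - rhs) / max(abs(lhs), abs(rhs), 1e-12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
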