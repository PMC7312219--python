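"""Shared test utilities: deterministic stub fitness tables and
brute-force Pareto oracles."""

import itertools

import numpy as np


def structured_lookup_table(n_channels: int, seed: int) -> dict:
    """Deterministic subset->accuracy table with the shape of a real
    wrapper fitness: descending channel weights with diminishing returns
    plus a small deterministic per-subset jitter."""
    rng = np.random.default_rng(seed)
    w = np.sort(rng.random(n_channels))[::-1] + 0.1
    lut = {}
    for r in range(1, n_channels + 1):
        for comb in itertools.combinations(range(n_channels), r):
            s = float(np.sum(w[list(comb)]))
            jitter = (hash(comb) % 1000) / 1e6  # int-tuple hash: stable across runs
            lut[comb] = round(float(1.0 - np.exp(-1.5 * s)) + jitter, 6)
    return lut


def exhaustive_pareto(lut: dict) -> list[tuple[int, float]]:
    """Brute-force best-accuracy-per-size front from a full lookup table."""
    best: dict[int, float] = {}
    for subset, acc in lut.items():
        no = len(subset)
        if no not in best or acc > best[no]:
            best[no] = acc
    front = []
    top = -np.inf
    for no in sorted(best):
        if best[no] > top:
            front.append((no, best[no]))
            top = best[no]
    return front


class StubScore:
    def __init__(self, accuracy, classifier_id="stub"):
        self.accuracy = accuracy
        self.classifier_id = classifier_id
        self.sensitivity = None
        self.specificity = None
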