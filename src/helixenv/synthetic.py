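"""Synthetic cohorts with the statistical structure the analysis assumes.

Chains carry a known ("truth") helix annotation; three assigner views are
derived from it by perturbing helix termini; descriptor values are baseline
noise plus a mean shift on helix residues.  Everything is deterministic for
a fixed master seed, with per-chain sub-streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from helixenv._errors import SizingError
from helixenv.types import ASSIGNERS, COIL_CODE, HELIX_CODE, ChainRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_LOGNORM_MEAN = math.exp(0.5)
_LOGNORM_SD = math.sqrt((math.e - 1.0) * math.e)


@dataclass
class SyntheticConfig:
    """Parameters of a synthetic cohort.

    ``baseline_mean``, ``baseline_sd``, ``inside_effect`` and
    ``correlation_loading`` may be scalars (broadcast over descriptors) or
    per-descriptor sequences.  ``inside_effect`` is expressed in units of
    the descriptor's baseline SD.
    """

    n_chains: int = 20
    chain_length_range: tuple[int, int] = (80, 120)
    helix_length: int = 12
    helices_per_chain: int = 1
    n_descriptors: int = 5
    baseline_mean: float | list[float] = 0.0
    baseline_sd: float | list[float] = 1.0
    inside_effect: float | list[float] = 0.0
    correlation_loading: float | list[float] | None = None
    nonnormal_fraction: float = 0.0
    assigner_disagreement_p: float = 0.0
    duplicate_fraction: float = 0.0
    mutation_rate: float = 0.02
    seed: int = 0
    descriptor_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("nonnormal_fraction", "assigner_disagreement_p",
                     "duplicate_fraction", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.helix_length < 5:
            raise ValueError(
                f"helix_length must be >= 5, got {self.helix_length}")
        if self.helices_per_chain < 1:
            raise ValueError("helices_per_chain must be >= 1")
        lo, hi = self.chain_length_range
        if lo > hi or lo < 1:
            raise ValueError(f"bad chain_length_range {self.chain_length_range}")
        if np.any(np.asarray(self.baseline_sd, dtype=float) <= 0):
            raise ValueError("baseline_sd entries must be > 0")
        # k helices of length L need k*L residues plus k-1 separators
        needed = (self.helices_per_chain * self.helix_length
                  + self.helices_per_chain - 1)
        if lo < needed:
            raise SizingError(
                f"chains of length {lo} cannot hold {self.helices_per_chain} "
                f"helices of length {self.helix_length} "
                f"(minimum {needed} residues)")
        if not self.descriptor_names:
            width = len(str(self.n_descriptors))
            self.descriptor_names = [
                f"d{i + 1:0{width}d}" for i in range(self.n_descriptors)]
        if len(self.descriptor_names) != self.n_descriptors:
            raise ValueError("descriptor_names length != n_descriptors")

    def _per_descriptor(self, value) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(value, dtype=float), (self.n_descriptors,)).copy()


def _place_helices(rng: np.random.Generator, chain_len: int,
                   k: int, L: int) -> list[tuple[int, int]]:
    """Choose k non-overlapping helix spans separated by >= 1 residue."""
    slack = chain_len - (k * L + (k - 1))
    # split the slack uniformly over the k+1 gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=k))
    gaps = np.diff(np.concatenate(([0], cuts, [slack])))
    spans = []
    pos = 0
    for i in range(k):
        pos += int(gaps[i]) + (1 if i > 0 else 0)
        spans.append((pos, pos + L - 1))
        pos += L
    return spans


def _paint(length: int, spans: list[tuple[int, int]]) -> str:
    ann = [COIL_CODE] * length
    for start, end in spans:
        for i in range(start, end + 1):
            ann[i] = HELIX_CODE
    return "".join(ann)


def _spans_of(annotation: str) -> list[tuple[int, int]]:
    spans, start = [], None
    for i, c in enumerate(annotation):
        if c == HELIX_CODE and start is None:
            start = i
        elif c != HELIX_CODE and start is not None:
            spans.append((start, i - 1))
            start = None
    if start is not None:
        spans.append((start, len(annotation) - 1))
    return spans


def _perturb_terminus(spans: list[tuple[int, int]], idx: int, which: str,
                      delta: int, chain_len: int) -> bool:
    """Try to move one terminus of spans[idx] by delta; return success.

    A move is rejected if it would empty the helix, leave the chain, or
    close the >=1-residue gap to a neighbouring helix.
    """
    start, end = spans[idx]
    if which == "start":
        new_start, new_end = start + delta, end
    else:
        new_start, new_end = start, end + delta
    if new_end < new_start:
        return False
    if new_start < 0 or new_end > chain_len - 1:
        return False
    if idx > 0 and spans[idx - 1][1] >= new_start - 1:
        return False
    if idx < len(spans) - 1 and spans[idx + 1][0] <= new_end + 1:
        return False
    spans[idx] = (new_start, new_end)
    return True


def make_assigner_views(truth: str, disagreement_p: float,
                        seed: int | np.random.Generator) -> dict[str, str]:
    """Derive three assigner annotation strings from a truth annotation.

    Each assigner independently, per helix terminus and with probability
    ``disagreement_p``, moves that terminus by one residue (direction
    chosen at random, falling back to the opposite direction when the
    preferred one would violate helix separation or chain bounds).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    chain_len = len(truth)
    truth_spans = _spans_of(truth)
    views: dict[str, str] = {}
    for role in ASSIGNERS:
        spans = list(truth_spans)
        for idx in range(len(spans)):
            for which in ("start", "end"):
                if rng.random() >= disagreement_p:
                    continue
                delta = int(rng.choice((-1, 1)))
                if not _perturb_terminus(spans, idx, which, delta, chain_len):
                    _perturb_terminus(spans, idx, which, -delta, chain_len)
        views[role] = _paint(chain_len, spans)
    return views


def _descriptor_values(rng: np.random.Generator, config: SyntheticConfig,
                       truth: str) -> np.ndarray:
    """(n_residues, n_descriptors) value matrix for one chain."""
    n = len(truth)
    d = config.n_descriptors
    mean = config._per_descriptor(config.baseline_mean)
    sd = config._per_descriptor(config.baseline_sd)
    effect = config._per_descriptor(config.inside_effect)

    n_heavy = int(round(config.nonnormal_fraction * d))
    z = rng.standard_normal((n, d))
    if n_heavy:
        # last n_heavy descriptors: standardized log-normal noise
        heavy = (np.exp(rng.standard_normal((n, n_heavy))) - _LOGNORM_MEAN
                 ) / _LOGNORM_SD
        z[:, d - n_heavy:] = heavy
    if config.correlation_loading is not None:
        lam = config._per_descriptor(config.correlation_loading)
        shared = rng.standard_normal((n, 1))
        z = lam * shared + np.sqrt(1.0 - lam**2) * z

    inside = np.array([c == HELIX_CODE for c in truth], dtype=float)
    return mean + sd * (effect * inside[:, None] + z)


def generate_cohort(
        config: SyntheticConfig) -> tuple[list[ChainRecord], pd.DataFrame]:
    """Generate chains, assigner views and a per-residue descriptor table.

    Returns the chain records (annotations keyed by assigner role, plus a
    ``truth`` entry) and a long-format table with columns ``chain_id``,
    ``residue_index`` (0-based) and one column per descriptor.
    """
    master = np.random.SeedSequence(config.seed)
    streams = [np.random.default_rng(s) for s in master.spawn(config.n_chains)]
    n_dup = int(round(config.duplicate_fraction * config.n_chains))
    n_orig = config.n_chains - n_dup
    if n_orig < 1:
        raise ValueError("duplicate_fraction leaves no original chains")

    lo, hi = config.chain_length_range
    records: list[ChainRecord] = []
    frames: list[pd.DataFrame] = []
    truths: list[str] = []
    sequences: list[str] = []
    width = len(str(config.n_chains))

    for i in range(config.n_chains):
        rng = streams[i]
        chain_id = f"C{i + 1:0{width}d}"
        if i < n_orig:
            chain_len = int(rng.integers(lo, hi + 1))
            spans = _place_helices(rng, chain_len, config.helices_per_chain,
                                   config.helix_length)
            truth = _paint(chain_len, spans)
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=chain_len))
        else:
            src = int(rng.integers(0, n_orig))
            truth = truths[src]
            seq = list(sequences[src])
            hits = rng.random(len(seq)) < config.mutation_rate
            for j in np.flatnonzero(hits):
                seq[j] = str(rng.choice(list(AMINO_ACIDS)))
            seq = "".join(seq)
        truths.append(truth)
        sequences.append(seq)

        annotations = make_assigner_views(
            truth, config.assigner_disagreement_p, rng)
        annotations["truth"] = truth
        records.append(ChainRecord(chain_id=chain_id, sequence=seq,
                                   annotations=annotations))

        values = _descriptor_values(rng, config, truth)
        frame = pd.DataFrame(values, columns=config.descriptor_names)
        frame.insert(0, "residue_index", np.arange(len(truth)))
        frame.insert(0, "chain_id", chain_id)
        frames.append(frame)

    table = pd.concat(frames, ignore_index=True)
    return records, table
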