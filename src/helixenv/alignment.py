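"""Positional alignment of equal-length helices and per-position profiles.

Helices of one length L are stacked so their spans coincide, the
observation field extends 32 residues past each terminus, and every
descriptor becomes an (instances x positions) matrix with 64 + L columns.
Cells beyond a chain end are gaps; flank cells that fall inside another
helix are helix-marked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from helixenv._errors import InputError
from helixenv.types import HELIX_CODE, ChainRecord, HelixInstance

GAP = "-"

#: Default flank width in residues on each side of the helix.
DEFAULT_FLANK = 32


def position_labels(length: int, flank: int = DEFAULT_FLANK) -> np.ndarray:
    """Axis labels: -flank..-1, then 1..L, then L+1..L+flank (no zero)."""
    pre = np.arange(-flank, 0)
    helix = np.arange(1, length + 1)
    post = np.arange(length + 1, length + flank + 1)
    return np.concatenate([pre, helix, post])


@dataclass
class AlignedEnsemble:
    """Equal-length helices aligned over positions -flank .. L+flank."""

    length: int
    flank: int
    instances: list[HelixInstance]
    positions: np.ndarray
    values: dict[str, np.ndarray]       # descriptor -> (n, P), NaN at gaps
    gap_mask: np.ndarray                # (n, P) True where no residue exists
    helix_mask: np.ndarray              # (n, P) True where residue is helical
    residues: np.ndarray                # (n, P) residue letters, '-' at gaps

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    @property
    def n_positions(self) -> int:
        return 2 * self.flank + self.length

    @property
    def helix_columns(self) -> slice:
        return slice(self.flank, self.flank + self.length)

    @property
    def flank_columns(self) -> np.ndarray:
        cols = np.ones(self.n_positions, dtype=bool)
        cols[self.helix_columns] = False
        return np.flatnonzero(cols)

    def descriptor(self, name: str) -> np.ndarray:
        try:
            return self.values[name]
        except KeyError:
            raise InputError(f"unknown descriptor {name!r}; available: "
                             f"{sorted(self.values)}")


def _chain_matrices(table: pd.DataFrame, descriptors: Sequence[str],
                    ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per chain: (dense (n_res, D) value array, residue-present mask)."""
    required = {"chain_id", "residue_index"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"descriptor table lacks columns {sorted(missing)}")
    out = {}
    for cid, grp in table.groupby("chain_id", sort=False):
        idx = grp["residue_index"].to_numpy(dtype=int)
        size = int(idx.max()) + 1 if idx.size else 0
        dense = np.full((size, len(descriptors)), np.nan)
        present = np.zeros(size, dtype=bool)
        dense[idx] = grp[list(descriptors)].to_numpy(dtype=float)
        present[idx] = True
        out[str(cid)] = (dense, present)
    return out


def align_ensemble(instances: Sequence[HelixInstance],
                   records: Mapping[str, ChainRecord],
                   table: pd.DataFrame,
                   descriptors: Sequence[str] | None = None,
                   flank: int = DEFAULT_FLANK,
                   role: str | None = None) -> AlignedEnsemble:
    """Stack same-length helices into an :class:`AlignedEnsemble`.

    ``role`` selects the annotation used for helix marking of flank
    residues (defaults to 'truth' when present, else the first annotation
    of each record).
    """
    if not instances:
        raise InputError("no instances to align")
    lengths = {h.length for h in instances}
    if len(lengths) > 1:
        raise InputError(f"mixed helix lengths {sorted(lengths)}; "
                         "an ensemble needs a single length")
    length = lengths.pop()
    if descriptors is None:
        descriptors = [c for c in table.columns
                       if c not in ("chain_id", "residue_index")]
    per_chain = _chain_matrices(table, descriptors)

    n = len(instances)
    p = 2 * flank + length
    gap_mask = np.ones((n, p), dtype=bool)
    helix_mask = np.zeros((n, p), dtype=bool)
    residues = np.full((n, p), GAP, dtype="<U1")
    values = {d: np.full((n, p), np.nan) for d in descriptors}

    for i, inst in enumerate(instances):
        record = records.get(inst.chain_id)
        if record is None:
            raise InputError(f"no chain record for {inst.chain_id!r}")
        ann_role = role or ("truth" if "truth" in record.annotations
                            else next(iter(record.annotations)))
        annotation = np.frombuffer(
            record.annotations[ann_role].encode(), dtype="S1")
        seq = np.frombuffer(record.sequence.encode(), dtype="S1")
        chain_len = len(record.sequence)
        try:
            dense, present = per_chain[inst.chain_id]
        except KeyError:
            raise InputError(f"no descriptor rows for chain {inst.chain_id!r}")
        r = inst.start - flank + np.arange(p)
        valid = (r >= 0) & (r < chain_len)
        rv = r[valid]
        if np.any(rv >= present.size) or not np.all(present[rv]):
            bad = rv[(rv >= present.size) | ~present[np.minimum(
                rv, present.size - 1)]][0]
            raise InputError(f"chain {inst.chain_id!r}: missing descriptor "
                             f"row for residue {int(bad)}")
        gap_mask[i, valid] = False
        residues[i, valid] = seq[rv].astype("U1")
        helix_mask[i, valid] = annotation[rv] == HELIX_CODE.encode()
        for k, d in enumerate(descriptors):
            values[d][i, valid] = dense[rv, k]
        helix_mask[i, flank:flank + length] = True

    return AlignedEnsemble(length=length, flank=flank,
                           instances=list(instances),
                           positions=position_labels(length, flank),
                           values=values, gap_mask=gap_mask,
                           helix_mask=helix_mask, residues=residues)


def position_profile(ensemble: AlignedEnsemble, descriptor: str,
                     ) -> pd.DataFrame:
    """Mean/SD/SEM, occupancy% and helical% per alignment position.

    Gap cells are excluded; positions with fewer than two observations
    report SD/SEM as missing (never zero).
    """
    mat = ensemble.descriptor(descriptor)
    n_total = ensemble.n_instances
    n = np.sum(~np.isnan(mat), axis=0)
    with np.errstate(invalid="ignore"):
        mean = np.where(n >= 1, np.nanmean(mat, axis=0), np.nan)
        sd = np.full(mat.shape[1], np.nan)
        ok = n >= 2
        sd[ok] = np.nanstd(mat[:, ok], axis=0, ddof=1)
    sem = sd / np.sqrt(np.maximum(n, 1))
    occupancy = 100.0 * np.sum(~ensemble.gap_mask, axis=0) / n_total
    helical = 100.0 * np.sum(ensemble.helix_mask, axis=0) / n_total
    return pd.DataFrame({
        "position": ensemble.positions,
        "mean": mean, "sd": sd, "sem": sem, "n": n,
        "occupancy_pct": occupancy, "helical_pct": helical,
    })


def logo_matrix(ensemble: AlignedEnsemble) -> pd.DataFrame:
    """Per-position amino-acid frequency matrix (gaps excluded from the
    denominator; all-gap columns are all-zero)."""
    letters = sorted({c for c in ensemble.residues.ravel() if c != GAP})
    freqs = np.zeros((ensemble.n_positions, len(letters)))
    for j in range(ensemble.n_positions):
        col = ensemble.residues[:, j]
        col = col[col != GAP]
        if col.size:
            for k, aa in enumerate(letters):
                freqs[j, k] = np.sum(col == aa) / col.size
    out = pd.DataFrame(freqs, columns=letters)
    out.insert(0, "position", ensemble.positions)
    return out


@dataclass
class EcdfTable:
    """Empirical distribution function Fn(x) = (1/n) sum 1[Xi <= x]."""

    values: np.ndarray          # sorted sample
    cumfrac: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float))
        if self.values.size == 0:
            raise ValueError("ECDF needs at least one observation")
        n = self.values.size
        self.cumfrac = np.arange(1, n + 1) / n

    def __call__(self, x) -> np.ndarray | float:
        idx = np.searchsorted(self.values, x, side="right")
        return idx / self.values.size

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "cumfrac": self.cumfrac})


def ecdf(values) -> EcdfTable:
    values = np.asarray(values, dtype=float)
    return EcdfTable(values[~np.isnan(values)])


def inside_outside_values(ensemble: AlignedEnsemble, descriptor: str,
                          granularity: str = "positions",
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Value sets for the helix span vs the flanks.

    'positions': per-position means (the default analysis granularity);
    'residues': raw non-gap cell values.
    """
    mat = ensemble.descriptor(descriptor)
    span = ensemble.helix_columns
    flanks = ensemble.flank_columns
    if granularity == "positions":
        with np.errstate(invalid="ignore"):
            means = np.nanmean(
                np.where(ensemble.gap_mask, np.nan, mat), axis=0)
        inside = means[span]
        outside = means[flanks]
    elif granularity == "residues":
        inside = mat[:, span][~ensemble.gap_mask[:, span]]
        outside = mat[:, flanks][~ensemble.gap_mask[:, flanks]]
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    return (inside[~np.isnan(inside)], outside[~np.isnan(outside)])


def ecdf_pair(ensemble: AlignedEnsemble, descriptor: str,
              granularity: str = "positions") -> tuple[EcdfTable, EcdfTable]:
    """Inside vs outside ECDFs for one descriptor."""
    inside, outside = inside_outside_values(ensemble, descriptor, granularity)
    return ecdf(inside), ecdf(outside)
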