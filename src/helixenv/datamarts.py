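"""Helix extraction, assigner consensus, redundancy removal and datamarts.

A datamart is a per-length compilation of helix instances drawn from one
protein class; it splits into an "exclusive" part (chains with a single
helix) and a "nonexclusive" part (chains with more than one), and the two
parts always add up to the combined mart.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align

from helixenv._errors import InputError
from helixenv.types import (
    CONSENSUS_MODES,
    HELIX_CODE,
    ChainRecord,
    Datamart,
    HelixInstance,
)

_HELIX_RUN = re.compile(f"{HELIX_CODE}+")

#: DSSP secondary-structure codes treated as alpha-helix.  G (3-10) and
#: I (pi) deliberately excluded; pass a wider set to include them.
ALPHA_CODES = frozenset("H")


def parse_dssp(text: str, helix_codes: frozenset[str] = ALPHA_CODES,
               ) -> dict[str, tuple[str, str]]:
    """Parse DSSP output text into per-chain (sequence, annotation) pairs.

    Only the residue table is read (columns: residue number, chain id,
    amino acid, summary structure code).  Chain-break records ('!') are
    kept as non-helix placeholder positions with sequence character 'X';
    chain terminators ('!*') merely separate chains.  Raises
    :class:`InputError` with a line number on malformed records.

    Implemented directly (rather than via Bio.PDB's DSSP reader) because
    break records and per-line error locations must be preserved.
    """
    lines = text.splitlines()
    try:
        start = next(i for i, ln in enumerate(lines)
                     if ln.lstrip().startswith("#  RESIDUE"))
    except StopIteration:
        raise InputError("not a DSSP file: residue table header not found")

    chains: dict[str, list[tuple[str, str]]] = {}
    for lineno, line in enumerate(lines[start + 1:], start=start + 2):
        if not line.strip():
            continue
        if len(line) < 14:
            raise InputError(f"line {lineno}: truncated DSSP record")
        aa = line[13]
        if aa != "!" and len(line) < 17:
            raise InputError(f"line {lineno}: truncated DSSP record")
        if aa == "!":
            if line[14] == "*":  # chain terminator
                continue
            chain_id = line[11].strip() or "_"
            chains.setdefault(chain_id, []).append(("X", "c"))
            continue
        chain_id = line[11].strip() or "_"
        try:
            int(line[5:10])
        except ValueError:
            raise InputError(f"line {lineno}: bad residue number "
                             f"{line[5:10]!r}")
        ss = line[16]
        code = HELIX_CODE if ss in helix_codes else "c"
        chains.setdefault(chain_id, []).append((aa, code))

    return {cid: ("".join(a for a, _ in rows), "".join(c for _, c in rows))
            for cid, rows in chains.items()}


def extract_helices(annotation: str, chain_id: str = "",
                    consensus_mode: str = "single") -> list[HelixInstance]:
    """Maximal runs of the helix code, ordered by start position."""
    return [HelixInstance(chain_id=chain_id, start=m.start(),
                          end=m.end() - 1, consensus_mode=consensus_mode)
            for m in _HELIX_RUN.finditer(annotation)]


def consensus_helices(record: ChainRecord, mode: str) -> list[HelixInstance]:
    """Helices whose start AND end coincide in every assigner of ``mode``."""
    try:
        roles = CONSENSUS_MODES[mode]
    except KeyError:
        raise InputError(f"unknown consensus mode {mode!r}; "
                         f"choose from {sorted(CONSENSUS_MODES)}")
    span_sets = []
    for role in roles:
        if role not in record.annotations:
            raise InputError(
                f"chain {record.chain_id}: no annotation for assigner "
                f"{role!r} required by mode {mode!r}")
        span_sets.append({h.span for h in
                          extract_helices(record.annotations[role])})
    common = set.intersection(*span_sets)
    return [HelixInstance(chain_id=record.chain_id, start=s, end=e,
                          consensus_mode=mode)
            for s, e in sorted(common)]


def classify_exclusivity(helices: Sequence[HelixInstance]) -> str:
    """'exclusive' for exactly one helix, 'nonexclusive' for more,
    'excluded' for none (the chain drops out of the datamarts)."""
    if len(helices) == 0:
        return "excluded"
    return "exclusive" if len(helices) == 1 else "nonexclusive"


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = 0.0
    return aligner


def pairwise_identity(seq1: str, seq2: str,
                      aligner: Align.PairwiseAligner | None = None) -> float:
    """Deterministic global-alignment identity: matches / alignment length.

    Matches m is the match-maximizing global alignment score (match 1,
    mismatch and gap 0), which is unique even when several alignments are
    co-optimal; the alignment length is taken canonically as
    len1 + len2 - m (each match one column, every other residue its own
    column), so identity is 1 exactly for identical sequences.
    """
    if not seq1 or not seq2:
        return 0.0
    aligner = aligner or _make_aligner()
    matches = float(aligner.score(seq1, seq2))
    return matches / (len(seq1) + len(seq2) - matches)


def cluster_redundancy(sequences: Mapping[str, str], level: float,
                       ) -> tuple[list[str], dict[str, str]]:
    """Greedy identity clustering; returns (representative ids, member->rep).

    Sequences are visited longest-first (ties keep input order); each joins
    the earliest representative with identity >= ``level``, else founds a
    new cluster.
    """
    if not 0.0 < level <= 1.0:
        raise ValueError(f"identity level must be in (0, 1], got {level}")
    aligner = _make_aligner()
    order = sorted(sequences, key=lambda k: -len(sequences[k]))
    reps: list[str] = []
    assignment: dict[str, str] = {}
    for key in order:
        seq = sequences[key]
        for rep in reps:
            if pairwise_identity(seq, sequences[rep], aligner) >= level:
                assignment[key] = rep
                break
        else:
            reps.append(key)
            assignment[key] = key
    return reps, assignment


def build_datamarts(records: Iterable[ChainRecord],
                    class_label: str | None = None,
                    consensus_mode: str = "pdb-dssp-stride",
                    redundancy_level: float | None = None,
                    name: str = "DM",
                    ) -> dict[str, Datamart]:
    """Class filter -> redundancy clustering -> consensus -> per-length counts.

    Returns {name: combined, name_e: exclusive, name_ne: nonexclusive};
    per length, combined counts equal exclusive + nonexclusive counts.
    Chains with no consensus helix are dropped.
    """
    records = list(records)
    if class_label is not None:
        records = [r for r in records if r.class_label == class_label]
    if redundancy_level is not None and records:
        reps, _ = cluster_redundancy(
            {r.chain_id: r.sequence for r in records}, redundancy_level)
        keep = set(reps)
        records = [r for r in records if r.chain_id in keep]

    marts = {name: Datamart(name=name),
             f"{name}_e": Datamart(name=f"{name}_e"),
             f"{name}_ne": Datamart(name=f"{name}_ne")}
    for record in records:
        helices = consensus_helices(record, consensus_mode)
        flavour = classify_exclusivity(helices)
        if flavour == "excluded":
            continue
        exclusive = flavour == "exclusive"
        sub = marts[f"{name}_e" if exclusive else f"{name}_ne"]
        for h in helices:
            inst = HelixInstance(chain_id=h.chain_id, start=h.start,
                                 end=h.end, exclusive=exclusive,
                                 consensus_mode=consensus_mode)
            for mart in (marts[name], sub):
                mart.members.append(inst)
                mart.counts[inst.length] = mart.counts.get(inst.length, 0) + 1
    return marts


def load_reference_counts() -> pd.DataFrame:
    """Packaged per-length helix counts for the two protein classes.

    Columns: length, DM1, DM1_e, DM1_ne, DM2, DM2_e, DM2_ne.  Serves as
    the reference accounting fixture for datamart totals.
    """
    ref = resources.files("helixenv.data").joinpath("helix_length_counts.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def datamart_summary(marts: Mapping[str, Datamart], name: str = "DM",
                     ) -> pd.DataFrame:
    """Per-length count table (length, n_total, n_exclusive, n_nonexclusive)."""
    lengths = sorted(marts[name].counts)
    return pd.DataFrame({
        "length": lengths,
        "n_total": [marts[name].counts[L] for L in lengths],
        "n_exclusive": [marts[f"{name}_e"].counts.get(L, 0) for L in lengths],
        "n_nonexclusive": [marts[f"{name}_ne"].counts.get(L, 0)
                           for L in lengths],
    })
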