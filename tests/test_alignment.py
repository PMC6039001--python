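import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helixenv import alignment
from helixenv._errors import InputError
from helixenv.alignment import (
    align_ensemble,
    ecdf,
    ecdf_pair,
    inside_outside_values,
    logo_matrix,
    position_labels,
    position_profile,
)
from helixenv.types import ChainRecord, HelixInstance


def _cohort(chains):
    """chains: list of (chain_id, annotation); constant sequence 'A',
    descriptor value = residue_index."""
    records, rows = {}, []
    for cid, ann in chains:
        records[cid] = ChainRecord(chain_id=cid, sequence="A" * len(ann),
                                   annotations={"truth": ann})
        for i in range(len(ann)):
            rows.append({"chain_id": cid, "residue_index": i, "d": float(i)})
    return records, pd.DataFrame(rows)


def _instances(records, length):
    out = []
    for cid, rec in records.items():
        ann = rec.annotations["truth"]
        start = ann.index("H")
        out.append(HelixInstance(chain_id=cid, start=start,
                                 end=start + length - 1))
    return out


class TestAlignEnsemble:
    def test_column_count_is_64_plus_length(self):
        ann = "c" * 40 + "H" * 12 + "c" * 40
        records, table = _cohort([(f"c{i}", ann) for i in range(5)])
        ens = align_ensemble(_instances(records, 12), records, table)
        assert ens.n_positions == 76
        assert ens.values["d"].shape == (5, 76)

    def test_position_labels_skip_zero(self):
        labels = position_labels(12)
        assert labels[0] == -32 and labels[31] == -1
        assert labels[32] == 1 and labels[43] == 12
        assert labels[44] == 13 and labels[-1] == 44
        assert 0 not in labels

    def test_helix_at_chain_start_gives_all_pre_gaps(self):
        ann = "H" * 12 + "c" * 40
        records, table = _cohort([("c0", ann)])
        ens = align_ensemble(
            [HelixInstance(chain_id="c0", start=0, end=11)], records, table)
        assert ens.gap_mask[0, :32].all()
        assert not ens.gap_mask[0, 32:].any()

    def test_downstream_helix_is_helix_marked(self):
        # second helix 3 residues after the first
        ann = "c" * 32 + "H" * 12 + "ccc" + "H" * 12 + "c" * 17
        records, table = _cohort([("c0", ann)])
        ens = align_ensemble(
            [HelixInstance(chain_id="c0", start=32, end=43)], records, table)
        post = slice(44, 76)
        marked = np.flatnonzero(ens.helix_mask[0, post]) + 44
        assert list(marked) == list(range(47, 59))

    def test_boundary_positions_never_helix_marked(self, signal_ensemble):
        ens = signal_ensemble
        left = ens.flank - 1
        right = ens.flank + ens.length
        nongap_left = ~ens.gap_mask[:, left]
        nongap_right = ~ens.gap_mask[:, right]
        assert not ens.helix_mask[nongap_left, left].any()
        assert not ens.helix_mask[nongap_right, right].any()

    def test_mixed_lengths_rejected(self):
        ann = "c" * 40 + "H" * 12 + "c" * 40
        records, table = _cohort([("c0", ann)])
        bad = [HelixInstance(chain_id="c0", start=40, end=51),
               HelixInstance(chain_id="c0", start=40, end=50)]
        with pytest.raises(InputError, match="mixed"):
            align_ensemble(bad, records, table)

    def test_missing_descriptor_row_named(self):
        ann = "c" * 40 + "H" * 12 + "c" * 40
        records, table = _cohort([("c0", ann)])
        table = table[table["residue_index"] != 45]
        with pytest.raises(InputError, match="c0.*45"):
            align_ensemble(_instances(records, 12), records, table)


class TestPositionProfile:
    def test_constant_values(self):
        ann = "c" * 40 + "H" * 12 + "c" * 40
        records, table = _cohort([(f"c{i}", ann) for i in range(4)])
        table["d"] = 7.0
        ens = align_ensemble(_instances(records, 12), records, table)
        profile = position_profile(ens, "d")
        assert (profile["mean"] == 7.0).all()
        assert (profile["sd"] == 0.0).all()
        assert (profile["sem"] == 0.0).all()

    def test_direct_arithmetic_with_gaps(self):
        # five instances, two gapped at one pre-flank position
        anns = ["c" * 33 + "H" * 12 + "c" * 33] * 3 + \
               ["c" * 31 + "H" * 12 + "c" * 35] * 2
        records, rows = {}, []
        values = iter([1.0, 2.0, 3.0])
        for k, ann in enumerate(anns):
            cid = f"c{k}"
            records[cid] = ChainRecord(chain_id=cid,
                                       sequence="A" * len(ann),
                                       annotations={"truth": ann})
            start = ann.index("H")
            v = next(values) if k < 3 else 0.0
            for i in range(len(ann)):
                # column -33+32 = first pre-flank position for k<3
                rows.append({"chain_id": cid, "residue_index": i,
                             "d": v if i == start - 32 else 0.0})
        table = pd.DataFrame(rows)
        instances = [HelixInstance(chain_id=f"c{k}", start=anns[k].index("H"),
                                   end=anns[k].index("H") + 11)
                     for k in range(5)]
        ens = align_ensemble(instances, records, table)
        profile = position_profile(ens, "d").iloc[0]
        assert profile["position"] == -32
        assert profile["n"] == 3
        assert profile["mean"] == pytest.approx(2.0)
        assert profile["sd"] == pytest.approx(1.0)
        assert profile["sem"] == pytest.approx(1.0 / np.sqrt(3))
        assert profile["occupancy_pct"] == pytest.approx(60.0)

    def test_occupancy_100_on_helix_span(self, signal_ensemble):
        profile = position_profile(signal_ensemble, "d1")
        span = slice(32, 44)
        assert (profile["occupancy_pct"].iloc[span] == 100.0).all()
        assert (profile["helical_pct"].iloc[span] == 100.0).all()

    def test_occupancy_nonincreasing_toward_ends(self, signal_ensemble):
        # single-helix chains: gaps only arise from chain termination
        occ = position_profile(signal_ensemble, "d1")["occupancy_pct"]
        pre = occ.iloc[:32].to_numpy()
        post = occ.iloc[44:].to_numpy()
        assert (np.diff(pre) >= 0).all()
        assert (np.diff(post) <= 0).all()

    def test_shift_equivariance(self, signal_cohort, signal_ensemble):
        config, records, table = signal_cohort
        shifted = table.copy()
        shifted["d1"] = shifted["d1"] + 5.0
        marts_records = {r.chain_id: r for r in records}
        ens2 = align_ensemble(signal_ensemble.instances, marts_records,
                              shifted)
        p1 = position_profile(signal_ensemble, "d1")
        p2 = position_profile(ens2, "d1")
        assert np.allclose(p2["mean"], p1["mean"] + 5.0, equal_nan=True)
        assert np.allclose(p2["sd"], p1["sd"], equal_nan=True)
        assert np.allclose(p2["occupancy_pct"], p1["occupancy_pct"])

    def test_sem_le_sd(self, signal_ensemble):
        profile = position_profile(signal_ensemble, "d2")
        ok = profile["sd"].notna()
        assert (profile.loc[ok, "sem"] <= profile.loc[ok, "sd"] + 1e-12).all()

    def test_unknown_descriptor(self, signal_ensemble):
        with pytest.raises(InputError, match="unknown descriptor"):
            position_profile(signal_ensemble, "nope")

    def test_profile_recovers_injected_shift(self, signal_ensemble):
        profile = position_profile(signal_ensemble, "d1")
        span = slice(32, 44)
        inside = profile["mean"].iloc[span]
        outside = profile["mean"].drop(profile.index[span]).dropna()
        diff = inside.mean() - outside.mean()
        sem = np.hypot(inside.sem(), outside.sem())
        assert abs(diff - 1.0) < 3 * max(sem, 0.1)


class TestLogo:
    def _ens(self, seqs):
        ann = "H" * 12
        records, rows = {}, []
        for k, seq in enumerate(seqs):
            cid = f"c{k}"
            records[cid] = ChainRecord(chain_id=cid, sequence=seq,
                                       annotations={"truth": ann})
            for i in range(12):
                rows.append({"chain_id": cid, "residue_index": i, "d": 0.0})
        instances = [HelixInstance(chain_id=f"c{k}", start=0, end=11)
                     for k in range(len(seqs))]
        return align_ensemble(instances, records, pd.DataFrame(rows))

    def test_unanimous_position(self):
        logo = logo_matrix(self._ens(["A" * 12] * 3))
        helix_rows = logo.iloc[32:44]
        assert (helix_rows["A"] == 1.0).all()

    def test_frequencies(self):
        seqs = ["A" + "A" * 11, "A" + "A" * 11, "C" + "A" * 11,
                "G" + "A" * 11]
        logo = logo_matrix(self._ens(seqs))
        row = logo.iloc[32]
        assert row["A"] == pytest.approx(0.5)
        assert row["C"] == pytest.approx(0.25)
        assert row["G"] == pytest.approx(0.25)

    def test_all_gap_position_zero(self):
        logo = logo_matrix(self._ens(["A" * 12] * 3))
        aa_cols = [c for c in logo.columns if c != "position"]
        assert logo.iloc[0][aa_cols].sum() == 0.0

    def test_occupied_rows_sum_to_one(self, signal_ensemble):
        logo = logo_matrix(signal_ensemble)
        aa_cols = [c for c in logo.columns if c != "position"]
        occupied = (~signal_ensemble.gap_mask).sum(axis=0) > 0
        sums = logo[aa_cols].sum(axis=1).to_numpy()
        assert np.allclose(sums[occupied], 1.0)


class TestEcdf:
    def test_fn_from_definition(self):
        table = ecdf([1.0, 2.0, 3.0])
        assert table(2.0) == pytest.approx(2.0 / 3.0)

    def test_below_min_zero(self):
        assert ecdf([1.0, 2.0, 3.0])(0.5) == 0.0

    def test_max_is_one(self):
        assert ecdf([4.0, 1.0, 2.0])(4.0) == 1.0

    def test_identical_pair_zero_gap(self, signal_ensemble):
        inside, _ = inside_outside_values(signal_ensemble, "d1")
        e1, e2 = ecdf(inside), ecdf(inside)
        grid = np.linspace(inside.min() - 1, inside.max() + 1, 50)
        assert np.max(np.abs(e1(grid) - e2(grid))) == 0.0

    def test_pair_granularities(self, signal_ensemble):
        for granularity in ("positions", "residues"):
            inside, outside = ecdf_pair(signal_ensemble, "d1", granularity)
            assert inside.cumfrac[-1] == 1.0
            assert outside.cumfrac[-1] == 1.0

    @given(st.lists(st.floats(-100, 100), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_valid_cdf(self, values):
        table = ecdf(values)
        assert np.all(np.diff(table.cumfrac) >= 0)
        assert table.cumfrac[-1] == pytest.approx(1.0)
        assert np.all((table.cumfrac > 0) & (table.cumfrac <= 1))
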