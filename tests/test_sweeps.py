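"""Window calling, DSS merging/union, summaries and the full scan."""

import numpy as np
import pandas as pd
import pytest

from sweepscan.simdata import SimulationConfig, SweepSpec
from sweepscan.sweeps import (Comparison, SweepParams, call_windows,
                              dss_summary, merge_to_dss, simulate_and_scan,
                              union_dss)


def _scores(z_fst, z_dpi, starts=None, size=40_000):
    n = len(z_fst)
    starts = starts if starts is not None else np.arange(n) * 20_000
    return pd.DataFrame({
        "chrom": ["chr1"] * n,
        "start": starts,
        "end": np.asarray(starts) + size,
        "n_sites": 10,
        "z_fst": z_fst,
        "z_dpi": z_dpi,
    })


def test_call_windows_strict_cutoffs():
    sc = _scores([6.0, 6.01, np.nan], [3.09, 3.10, 2.0])
    sig = call_windows(sc)
    assert list(sig["fst"]["start"]) == [20_000]     # 6.0 is NOT significant
    assert list(sig["dpi"]["start"]) == [20_000]     # 3.10 is, 3.09 is not


def test_call_windows_empty_when_nothing_exceeds():
    sig = call_windows(_scores([1.0, 2.0], [0.5, -1.0]))
    assert sig["fst"].empty and sig["dpi"].empty
    final, _ = union_dss(merge_to_dss(sig["fst"], "fst"),
                         merge_to_dss(sig["dpi"], "dpi"))
    assert final.empty


def _windows(intervals, z=10.0):
    return pd.DataFrame({
        "chrom": ["chr1"] * len(intervals),
        "start": [s for s, _ in intervals],
        "end": [e for _, e in intervals],
        "z_fst": z, "z_dpi": z,
    })


def test_merge_overlapping_windows():
    dss = merge_to_dss(_windows([(0, 40_000), (20_000, 60_000)]), "fst")
    assert len(dss) == 1
    assert (dss.iloc[0]["start"], dss.iloc[0]["end"]) == (0, 60_000)
    assert dss.iloc[0]["n_windows"] == 2


def test_abutting_windows_not_merged():
    dss = merge_to_dss(_windows([(0, 40_000), (40_000, 80_000)]), "fst")
    assert len(dss) == 2


def test_transitive_merge():
    dss = merge_to_dss(
        _windows([(0, 40_000), (20_000, 60_000), (40_000, 80_000)]), "fst")
    assert len(dss) == 1
    assert (dss.iloc[0]["start"], dss.iloc[0]["end"]) == (0, 80_000)
    assert dss.iloc[0]["n_windows"] == 3


def test_merge_idempotent():
    once = merge_to_dss(
        _windows([(0, 40_000), (20_000, 60_000), (100_000, 140_000)]), "fst")
    twice = merge_to_dss(once)
    pd.testing.assert_frame_equal(
        once[["chrom", "start", "end"]], twice[["chrom", "start", "end"]])


def test_merge_respects_chromosomes():
    win = _windows([(0, 40_000)])
    win2 = win.copy()
    win2["chrom"] = "chr2"
    dss = merge_to_dss(pd.concat([win, win2], ignore_index=True), "fst")
    assert len(dss) == 2


def test_union_overlapping_cross_method():
    final, _ = union_dss(merge_to_dss(_windows([(0, 60_000)]), "fst"),
                         merge_to_dss(_windows([(40_000, 100_000)]), "dpi"))
    assert len(final) == 1
    assert (final.iloc[0]["start"], final.iloc[0]["end"]) == (0, 100_000)
    assert final.iloc[0]["method"] == "dpi+fst"


def test_union_disjoint_inputs_concatenate():
    fst = merge_to_dss(_windows([(0, 40_000), (100_000, 140_000),
                                 (200_000, 240_000)]), "fst")
    dpi = merge_to_dss(_windows([(300_000, 340_000), (400_000, 440_000)]),
                       "dpi")
    final, overlap = union_dss(fst, dpi)
    assert len(final) == 5
    assert overlap == {"fst_overlapped_by_dpi": 0.0,
                       "dpi_overlapped_by_fst": 0.0}


def test_union_with_empty_side_is_identity():
    fst = merge_to_dss(_windows([(0, 40_000), (100_000, 140_000)]), "fst")
    final, _ = union_dss(fst, merge_to_dss(_windows([]), "dpi"))
    pd.testing.assert_frame_equal(
        final[["chrom", "start", "end"]], fst[["chrom", "start", "end"]])
    assert (final["method"] == "fst").all()


def test_union_commutative_in_intervals():
    fst = merge_to_dss(_windows([(0, 60_000), (200_000, 240_000)]), "fst")
    dpi = merge_to_dss(_windows([(40_000, 100_000)]), "dpi")
    f1, _ = union_dss(fst, dpi)
    f2, _ = union_dss(dpi, fst)
    pd.testing.assert_frame_equal(f1[["chrom", "start", "end"]],
                                  f2[["chrom", "start", "end"]])


def test_dss_summary_values():
    dss = pd.DataFrame({
        "chrom": ["chr1"] * 3,
        "start": [0, 100_000, 300_000],
        "end": [40_000, 160_000, 500_000],
        "n_windows": [1, 2, 5],
    })
    s = dss_summary(dss, genome_size=10_000_000)
    assert s["median_length"] == 60_000
    assert s["frac_shorter_than_threshold"] == pytest.approx(2 / 3)
    assert s["genome_fraction"] == pytest.approx(0.03)
    with pytest.raises(ValueError):
        dss_summary(dss, genome_size=0)


def test_comparison_validation():
    with pytest.raises(ValueError):
        Comparison("bad", ("A",), ("A", "B"))
    with pytest.raises(ValueError):
        Comparison("bad", (), ("B",))


def test_significant_windows_covered_by_final_dss():
    cfg = SimulationConfig(
        chrom_lengths={"chr1": 2_000_000},
        sweeps=(SweepSpec("chr1", 500_000, 800_000, 1),),
        seed=29,
    )
    res = simulate_and_scan(cfg, SweepParams(n_permutations=10))
    sig = call_windows(res["windows"])
    dss = res["dss"]
    for frame in sig.values():
        for w in frame.itertuples():
            inside = ((dss["chrom"] == w.chrom) & (dss["start"] <= w.start)
                      & (dss["end"] >= w.end))
            assert inside.sum() == 1
    assert len(res["dss"]) <= len(res["dss_fst"]) + len(res["dss_dpi"])


def test_run_comparison_deterministic_outputs(tiny_cohort, tmp_path):
    from sweepscan.sweeps import run_comparison

    cfg, paths = tiny_cohort
    comp = Comparison("G0_vs_G1", ("G0",), ("G1",))
    params = SweepParams(n_permutations=8)
    outs = []
    for name in ("run_a", "run_b"):
        d = tmp_path / name
        run_comparison(paths["vcf"], paths["pop_map"], comp, params,
                       seed=3, out_dir=str(d))
        outs.append((d / "dss.tsv").read_bytes())
        assert (d / "manifest.json").exists()
        assert (d / "windows.tsv").exists()
    assert outs[0] == outs[1]


def test_scan_recovers_planted_sweep(tiny_cohort):
    from sweepscan.annotate import interval_overlap
    from sweepscan.sweeps import run_comparison

    cfg, paths = tiny_cohort
    res = run_comparison(paths["vcf"], paths["pop_map"],
                         Comparison("G0_vs_G1", ("G0",), ("G1",)),
                         SweepParams(n_permutations=10), seed=5)
    truth = [(c, s, e) for c, s, e, _ in cfg.truth().intervals]
    dss = [(r.chrom, int(r.start), int(r.end), i)
           for i, r in enumerate(res["dss"].itertuples())]
    q_frac, _, _ = interval_overlap(truth, dss)
    assert q_frac == 1.0
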