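"""Variant selection, IDW gridding, masking and map rendering."""

import io

import numpy as np
import pandas as pd
import pytest

from hlakit.fixtures import FixtureSpec, make_alignment_fixture, make_frequency_fixture
from hlakit.freqmap import (
    AlignmentCache,
    FrequencyDataError,
    LowFrequencyError,
    NotObservedError,
    genotype_frequencies,
    grid_frequencies,
    haversine_km,
    palm,
    read_frequency_table,
    read_haplotype_table,
    render_map,
    select_variant,
)


def _freq_df(rows):
    df = pd.DataFrame(
        rows,
        columns=["popname", "latit", "longit", "locus", "allele",
                 "frequency", "sample_size", "complex"],
    )
    df["migrant"] = df["complex"].str.lower().isin({"mig"})
    return df


THREE_POPS = _freq_df(
    [
        ["Berlin", 52.5, 13.4, "A", "A*01:01", 0.1, 200, ""],
        ["Berlin", 52.5, 13.4, "A", "A*02:01", 0.2, 200, ""],
        ["Nairobi", -1.3, 36.8, "A", "A*02:01", 0.5, 150, ""],
        ["Tokyo", 35.7, 139.7, "A", "A*01:01", 0.3, 300, ""],
        ["Tokyo", 35.7, 139.7, "A", "A*02:01", 0.1, 300, ""],
    ]
)


def test_allele_points_are_frequencies_with_zero_for_typed_absent():
    points, audit = select_variant("A*01:01", THREE_POPS, kind="allele")
    values = points.set_index("population")["value"].to_dict()
    assert values == {"Berlin": 0.1, "Nairobi": 0.0, "Tokyo": 0.3}
    assert audit["max_point_value"] == pytest.approx(0.3)


def test_motif_points_sum_matching_allele_frequencies():
    # both fixture alleles share the motif -> per-population sums
    prot = make_alignment_fixture(FixtureSpec(seed=0), align_type="prot")[1]
    table = _freq_df(
        [
            ["P1", 10.0, 10.0, prot.locus, "X*01:01", 0.1, 100, ""],
            ["P1", 10.0, 10.0, prot.locus, "X*02:02", 0.2, 100, ""],
        ]
    )
    # craft a protein table where two 2-field names carry residue Q at pos 1
    from hlakit.imgt_io import parse_alignment

    prot = parse_alignment(
        " Prot   1\n X*01:01  QWER\n X*02:02  ----\n X*03:03  L---\n", "prot"
    )
    points, audit = select_variant(
        f"{prot.locus}*1Q", table.assign(locus=prot.locus), kind="motif",
        prot_table=prot,
    )
    assert points["value"].tolist() == [pytest.approx(0.3)]
    assert audit["matched_alleles"] == ["X*01:01", "X*02:02"]


def _truncate_name(raw, k):
    from hlakit.names import AlleleName

    return AlleleName.parse(raw).truncate(k).raw


def test_haplotype_points_match_bruteforce_row_filter(frequency_fixture):
    _, haplo, _ = frequency_fixture
    some = haplo.iloc[0]["haplotype"].split("~")
    spec = "~".join(_truncate_name(a, 2) for a in some)
    points, _ = select_variant(spec, haplo, kind="haplotype")
    terms = spec.split("~")

    def oracle(pop_rows):
        total = 0.0
        for _, r in pop_rows.iterrows():
            parts = {a.split("*")[0]: a for a in r["haplotype"].split("~")}
            if all(_truncate_name(parts[t.split("*")[0]], 2) == t for t in terms):
                total += r["frequency"]
        return total

    assert not points.empty
    for _, p in points.iterrows():
        rows = haplo[haplo["population"] == p["population"]]
        assert p["value"] == pytest.approx(oracle(rows))


def test_haplotype_truncation_is_monotone(frequency_fixture):
    """Two-field extraction covers at least the three-field frequencies."""
    _, haplo, _ = frequency_fixture
    three_field_pops = haplo[haplo["haplotype"].str.count(":") >= 4]
    fine = three_field_pops.iloc[0]["haplotype"]
    coarse = "~".join(_truncate_name(a, 2) for a in fine.split("~"))
    fine_pts, _ = select_variant(fine, haplo, kind="haplotype")
    coarse_pts, _ = select_variant(coarse, haplo, kind="haplotype")
    merged = fine_pts.merge(coarse_pts, on="population", suffixes=("_f", "_c"))
    assert not merged.empty
    assert (merged["value_c"] >= merged["value_f"] - 1e-12).all()


def test_all_migrant_dataset_is_refused():
    df = THREE_POPS.assign(complex="mig", migrant=True)
    with pytest.raises(NotObservedError):
        select_variant("A*01:01", df, kind="allele", filter_migrant=True)


def test_low_frequency_needs_explicit_opt_in():
    df = THREE_POPS.copy()
    df["frequency"] = df["frequency"] * 1e-4
    with pytest.raises(LowFrequencyError):
        select_variant("A*01:01", df, kind="allele")
    points, _ = select_variant("A*01:01", df, kind="allele", generate_low_freq=True)
    assert len(points) == 3


def test_unobserved_allele_is_distinguishable():
    with pytest.raises(NotObservedError, match="not observed"):
        select_variant("A*33:33", THREE_POPS, kind="allele")


# ---------------------------------------------------------------------------
# table readers


def test_frequency_reader_flags_migrant_codes_and_validates():
    text = (
        "popname\tlatit\tlongit\tlocus\tallele\tfrequency\tsample_size\tcomplex\n"
        "P1\t10\t20\tA\tA*01:01\t0.4\t100\t\n"
        "P2\t-5\t30\tA\tA*01:01\t0.2\t80\tmig\n"
    )
    df = read_frequency_table(io.StringIO(text))
    assert df["migrant"].tolist() == [False, True]
    bad = text + "P1\t10\t20\tA\tA*02:01\t0.7\t100\t\n"  # sums to 1.1
    with pytest.raises(FrequencyDataError, match="sum"):
        read_frequency_table(io.StringIO(bad))


def test_haplotype_reader_rejects_mixed_locus_sets():
    text = (
        "population\thaplotype\tfrequency\tsample_size\tlatit\tlongit\n"
        "P1\tA*01:01~B*08:01\t0.2\t100\t10\t20\n"
        "P1\tA*01:01~C*07:01\t0.1\t100\t10\t20\n"
    )
    with pytest.raises(FrequencyDataError, match="locus sets"):
        read_haplotype_table(io.StringIO(text))


# ---------------------------------------------------------------------------
# gridding


def _points(rows):
    return pd.DataFrame(rows, columns=["population", "latitude", "longitude", "value"])


def test_single_point_gives_constant_field_within_cutoff():
    pts = _points([["P", 48.0, 10.0, 0.25]])
    grid = grid_frequencies(pts, resolution=3.0, mask_sea=False, cutoff_km=1500)
    vals = grid.values.compressed()
    assert np.allclose(vals, 0.25)
    # cells beyond the cutoff are masked
    far = grid.value_at(-40.0, -150.0)
    assert np.isnan(far) or grid.values.mask[
        np.argmin(np.abs(grid.lats - (-40.0))), np.argmin(np.abs(grid.lons - (-150.0)))
    ]


def test_two_equal_points_give_uniform_field_between_them():
    pts = _points([["P1", 45.0, 0.0, 0.4], ["P2", 45.0, 20.0, 0.4]])
    grid = grid_frequencies(pts, resolution=2.0, mask_sea=False)
    assert np.allclose(grid.values.compressed(), 0.4)


def test_grid_is_exact_at_support_points_and_bounded(frequency_fixture):
    freq, _, _ = frequency_fixture
    points, _ = select_variant("A*01:01", freq, kind="allele")
    grid = grid_frequencies(points, resolution=2.0)
    lo, hi = points["value"].min(), points["value"].max()
    for _, p in points.iterrows():
        i = np.argmin(np.abs(grid.lats - p["latitude"]))
        j = np.argmin(np.abs(grid.lons - p["longitude"]))
        assert not grid.values.mask[i, j]
        cell = grid.value_at(p["latitude"], p["longitude"])
        others = points[points["population"] != p["population"]]
        shares_cell = any(
            np.argmin(np.abs(grid.lats - o["latitude"])) == i
            and np.argmin(np.abs(grid.lons - o["longitude"])) == j
            for _, o in others.iterrows()
        )
        if not shares_cell:
            assert cell == pytest.approx(p["value"], abs=1e-12)
    vals = grid.values.compressed()
    assert vals.min() >= lo - 1e-12 and vals.max() <= hi + 1e-12


def test_sea_cells_are_masked_land_cells_are_not():
    pts = _points([["P", 48.0, 10.0, 0.3]])
    grid = grid_frequencies(pts, resolution=2.0, cutoff_km=4000, mask_sea=True)
    mid_atlantic = (
        np.argmin(np.abs(grid.lats - 30.0)), np.argmin(np.abs(grid.lons - (-40.0)))
    )
    central_europe = (
        np.argmin(np.abs(grid.lats - 50.0)), np.argmin(np.abs(grid.lons - 15.0))
    )
    assert bool(grid.values.mask[mid_atlantic])
    assert not bool(grid.values.mask[central_europe])


def test_scale_modes():
    pts = _points([["P1", 45.0, 0.0, 0.4], ["P2", 40.0, 10.0, 0.1]])
    assert grid_frequencies(pts, resolution=5.0, mask_sea=False).vmax == 0.4
    assert grid_frequencies(pts, resolution=5.0, mask_sea=False,
                            scale_mode="unit").vmax == 1.0


def test_zero_points_is_an_error():
    with pytest.raises(FrequencyDataError):
        grid_frequencies(_points([]), resolution=5.0)


def test_haversine_known_distance():
    # quarter of the equator
    assert haversine_km(0.0, 0.0, 0.0, 90.0) == pytest.approx(10007.5, rel=0.01)


# ---------------------------------------------------------------------------
# rendering and composition


def test_render_color_and_greyscale_share_mask(tmp_path):
    pts = _points([["P", 48.0, 10.0, 0.3]])
    grid = grid_frequencies(pts, resolution=4.0)
    p1 = render_map(grid, tmp_path / "m.png", color_mode="color")
    p2 = render_map(grid, tmp_path / "m_grey.svg", color_mode="greyscale")
    assert p1.stat().st_size > 0 and p2.stat().st_size > 0
    # the mask lives on the grid, shared by construction between renders
    assert grid.values.mask.any()


def test_render_unwritable_path_errors():
    pts = _points([["P", 48.0, 10.0, 0.3]])
    grid = grid_frequencies(pts, resolution=6.0)
    with pytest.raises(FileNotFoundError):
        render_map(grid, "no/such/dir/map.png")


def test_palm_composes_the_three_stages(frequency_fixture, tmp_path):
    freq, _, truth = frequency_fixture
    result = palm("A*01:01", freq, kind="allele", resolution=3.0,
                  out_path=tmp_path / "a.png")
    points, _ = select_variant("A*01:01", freq, kind="allele")
    manual = grid_frequencies(points, resolution=3.0)
    assert np.array_equal(
        result.grid.values.filled(-1), manual.values.filled(-1)
    )
    assert result.image_path.stat().st_size > 0
    assert result.audit["vmax"] == manual.vmax


def test_palm_unit_scale_maps_share_colorbar_maximum(frequency_fixture):
    freq, _, _ = frequency_fixture
    r1 = palm("A*01:01", freq, kind="allele", map_scale=False, resolution=5.0)
    r2 = palm("A*02:21", freq, kind="allele", map_scale=False, resolution=5.0) \
        if (freq["allele"] == "A*02:21").any() else None
    assert r1.grid.vmax == 1.0
    if r2 is not None:
        assert r2.grid.vmax == r1.grid.vmax


def test_palm_motif_maps_reuse_cached_alignments(frequency_fixture):
    freq, _, _ = frequency_fixture
    _, prot = make_alignment_fixture(FixtureSpec(seed=105, loci=("A",)),
                                     align_type="prot")
    builds = []

    def loader(locus):
        builds.append(locus)
        return prot

    cache = AlignmentCache(loader)
    ref = prot.rows[prot.reference_allele]
    usable = next(
        (prot.column_labels[j], ref[j])
        for j in range(prot.n_columns) if ref[j] not in ".*"
    )
    motif = f"A*{usable[0]}{usable[1]}"
    for _ in range(3):
        try:
            palm(motif, freq, kind="motif", alignments=cache, resolution=5.0,
                 generate_low_freq=True)
        except NotObservedError:
            break
    assert cache.n_builds == 1


def test_genotype_frequency_estimates():
    est = genotype_frequencies(0.6, 0.4)
    assert est["hom"] == pytest.approx(0.36)
    assert est["het"] == pytest.approx(0.48)
    assert est["hom_other"] == pytest.approx(0.16)
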