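"""Evaluation metrics: worked examples enumerated by hand, arithmetic
identities, and published-table consistency checks."""

import numpy as np
import pytest

from catchlink import evaluation, geodata_io
from catchlink.evaluation import (
    appropriateness,
    clusters_linked,
    compare_methods,
    contraceptive_mix,
    links_per_cluster,
    method_report,
    round_half_up,
    true_source_linked,
    weighted_overall,
)
from catchlink.model import (
    FacilityKind,
    IntegrityError,
    LastSource,
    LinkageResult,
    LinkMethod,
    Operator,
    Respondent,
    ValidationError,
)

from conftest import make_point


def _result(links, method=LinkMethod.BUFFER, radius=5000.0):
    return LinkageResult(method=method, radius_m=radius, links={k: frozenset(v) for k, v in links.items()})


@pytest.fixture
def three_units():
    pts = [
        make_point("U1", FacilityKind.HOSPITAL, 34.0, -13.0),
        make_point("U1P", FacilityKind.HEALTH_POST, 34.01, -13.0, parent="U1"),
        make_point("U2", FacilityKind.HEALTH_CENTER, 34.1, -13.0),
        make_point("U3", FacilityKind.HEALTH_CENTER, 34.2, -13.0, operator=Operator.CHAM),
    ]
    return geodata_io.build_facility_units(pts)


class TestClustersLinked:
    def test_all_linked(self):
        n, pct = clusters_linked(_result({"a": {"U1"}, "b": {"U2"}}))
        assert (n, pct) == (2, 100.0)

    def test_published_majority_share(self):
        # 529 of 817 clusters linked -> 64.7%
        links = {f"c{i}": ({"U1"} if i < 529 else set()) for i in range(817)}
        n, pct = clusters_linked(_result(links))
        assert n == 529
        assert round_half_up(pct, 1) == 64.7

    def test_zero_clusters_rejected(self):
        with pytest.raises(ValidationError):
            clusters_linked(_result({}))


class TestLinksPerCluster:
    def test_every_cluster_single_link(self):
        mean, sd = links_per_cluster(_result({"a": {"U1"}, "b": {"U2"}, "c": {"U1"}}))
        assert (round_half_up(mean, 1), round_half_up(sd, 2)) == (1.0, 0.0)

    def test_mean_over_linked_only_vs_all(self):
        res = _result({"a": {"U1"}, "b": {"U1", "U2"}, "c": {"U1", "U2", "U3"}, "d": set()})
        mean, _ = links_per_cluster(res, linked_only=True)
        mean_all, _ = links_per_cluster(res, linked_only=False)
        assert mean == pytest.approx(2.0)
        assert mean_all == pytest.approx(1.5)

    def test_population_sd_matches_independent_tally(self):
        rng = np.random.default_rng(2)
        sizes = rng.integers(1, 9, size=200)
        res = _result({f"c{i}": {f"U{k}" for k in range(s)} for i, s in enumerate(sizes)})
        mean, sd = links_per_cluster(res)
        assert mean == pytest.approx(sizes.mean())
        assert sd == pytest.approx(sizes.std())

    def test_no_linked_clusters_rejected(self):
        with pytest.raises(ValidationError):
            links_per_cluster(_result({"a": set()}))


class TestAppropriateness:
    def test_hand_enumerated_roster(self, three_units):
        # U1 offers gov hospital + gov post, U2 gov health center, U3 CHAM
        res = _result({"CL1": {"U1", "U2"}, "CL2": {"U3"}, "CL3": set()})
        women = [
            Respondent("R1", "CL1", True, LastSource.GOV_HOSPITAL),       # match via U1
            Respondent("R2", "CL1", True, LastSource.CHAM),               # no CHAM linked
            Respondent("R3", "CL2", True, LastSource.GOV_HEALTH_CENTER),  # U3 is CHAM-run
            Respondent("R4", "CL2", True, LastSource.CHAM),               # match via U3
            Respondent("R5", "CL3", True, LastSource.GOV_HEALTH_POST),    # unlinked cluster
            Respondent("R6", "CL1", True, LastSource.GOV_HEALTH_POST),    # match via U1's post
        ]
        per_source, overall = appropriateness(res, women, three_units)
        assert overall == pytest.approx(50.0)
        assert per_source[LastSource.GOV_HOSPITAL] == (1, pytest.approx(100.0))
        assert per_source[LastSource.GOV_HEALTH_CENTER] == (1, pytest.approx(0.0))
        assert per_source[LastSource.GOV_HEALTH_POST] == (2, pytest.approx(50.0))
        assert per_source[LastSource.CHAM] == (2, pytest.approx(50.0))

    def test_nonusers_and_unlinkable_excluded(self, three_units):
        res = _result({"CL1": {"U1"}})
        women = [
            Respondent("R1", "CL1", True, LastSource.GOV_HOSPITAL),
            Respondent("R2", "CL1", False, LastSource.NONE),
            Respondent("R3", "CL1", True, LastSource.OTHER_UNLINKABLE),
        ]
        per_source, overall = appropriateness(res, women, three_units)
        assert sum(n for n, _ in per_source.values()) == 1
        assert overall == pytest.approx(100.0)

    def test_respondent_outside_result_rejected(self, three_units):
        res = _result({"CL1": {"U1"}})
        women = [Respondent("R1", "CL9", True, LastSource.CHAM)]
        with pytest.raises(IntegrityError):
            appropriateness(res, women, three_units)

    def test_overall_equals_weighted_per_source(self, full_landscape, three_units):
        from catchlink import linkage

        land = full_landscape
        res = linkage.link_closest(land.clusters, land.service_points, land.units, land.projector)
        per_source, overall = appropriateness(res, land.respondents, land.units)
        assert overall == pytest.approx(weighted_overall(per_source), abs=1e-9)


class TestPublishedTableArithmetic:
    """The published summary rows are weighted averages of their per-source
    rates; recomputing them through the same code is an exact cross-check."""

    # per-source rates (hospital, health center, CHAM, post) and counts
    ROWS = {
        "closest": ((51.6, 70.6, 60.6, 72.6), 64.8),
        "buffer": ((47.9, 54.1, 62.3, 36.4), 51.9),
        "admin": ((90.7, 100.0, 99.7, 100.0), 97.5),
        "catchment": ((72.9, 96.2, 82.4, 97.6), 88.9),
    }
    COUNTS = (2287, 4948, 653, 552)

    @pytest.mark.parametrize("method", list(ROWS))
    def test_overall_from_per_source_rows(self, method):
        rates, expected = self.ROWS[method]
        per_source = {
            src: (n, pct)
            for src, n, pct in zip(
                (LastSource.GOV_HOSPITAL, LastSource.GOV_HEALTH_CENTER, LastSource.CHAM, LastSource.GOV_HEALTH_POST),
                self.COUNTS,
                rates,
            )
        }
        assert round_half_up(weighted_overall(per_source), 1) == expected

    def test_denominator_sums_to_total(self):
        assert sum(self.COUNTS) == 8440


class TestTrueSourceLinked:
    def test_matches_independent_tally(self, three_units):
        res = _result({"CL1": {"U1", "U2"}, "CL2": {"U3"}})
        women = [
            Respondent("R1", "CL1", True, LastSource.GOV_HOSPITAL),
            Respondent("R2", "CL1", True, LastSource.GOV_HEALTH_CENTER),
            Respondent("R3", "CL2", True, LastSource.CHAM),
        ]
        truth = {"R1": "U1", "R2": "U3", "R3": "U3"}
        # R1: U1 linked -> hit; R2: U3 not in CL1's set -> miss; R3: hit
        assert true_source_linked(res, truth, women) == pytest.approx(100.0 * 2 / 3)

    def test_missing_truth_rejected(self, three_units):
        res = _result({"CL1": {"U1"}})
        with pytest.raises(ValidationError):
            true_source_linked(res, {}, [])


class TestContraceptiveMix:
    def test_share_from_published_counts(self):
        # 4392 of 8440 included users on injections -> 52.0%
        assert round_half_up(100.0 * 4392 / 8440, 1) == 52.0

    def test_columns_sum_to_hundred(self, full_landscape):
        mix = contraceptive_mix(full_landscape.respondents)
        for col in ("included_pct", "ineligible_pct"):
            assert mix[col].sum() == pytest.approx(100.0, abs=0.2)

    def test_single_method_is_hundred_percent(self):
        women = [Respondent(f"R{i}", "CL1", True, LastSource.CHAM, method="pill") for i in range(5)]
        mix = contraceptive_mix(women)
        assert mix.loc[mix["method"] == "pill", "included_pct"].item() == pytest.approx(100.0)


class TestCompareMethods:
    def test_mismatched_cluster_sets_rejected(self, three_units):
        r1 = _result({"CL1": {"U1"}}, method=LinkMethod.CLOSEST)
        r2 = _result({"CL2": {"U1"}}, method=LinkMethod.ADMIN)
        with pytest.raises(IntegrityError):
            compare_methods([r1, r2], [], three_units)

    def test_report_renders_all_methods(self, full_landscape):
        from catchlink import catchments, linkage

        land = full_landscape
        areas = catchments.build_catchments(land.service_points, land.units, land.region, land.projector)
        results = [
            linkage.link_closest(land.clusters, land.service_points, land.units, land.projector),
            linkage.link_buffer(land.clusters, land.service_points, land.units, land.projector, 5000.0),
            linkage.link_admin(land.clusters, land.service_points, land.units),
            linkage.link_catchment(land.clusters, areas, land.projector, 5000.0,
                                   points=land.service_points, units=land.units),
        ]
        report = compare_methods(results, land.respondents, land.units, land.ground_truth())
        assert list(report["method"]) == ["closest", "buffer", "admin", "catchment"]
        assert (report["overall_pct_appropriate"] <= 100.0).all()
        assert (report["n_linked"] <= report["n_clusters"]).all()
        text = evaluation.render_text(report)
        assert "catchment" in text

    def test_single_district_admin_dominates(self):
        from catchlink import linkage, synthetic

        p = synthetic.LandscapeParams(seed=13, n_districts=1).scaled(0.08)
        p = synthetic.LandscapeParams(**{**p.__dict__, "n_districts": 1})
        land = synthetic.generate_landscape(p)
        res_admin = linkage.link_admin(land.clusters, land.service_points, land.units)
        res_closest = linkage.link_closest(land.clusters, land.service_points, land.units, land.projector)
        _, overall_admin = appropriateness(res_admin, land.respondents, land.units)
        _, overall_closest = appropriateness(res_closest, land.respondents, land.units)
        assert overall_admin >= overall_closest
        # with one district every cluster links every public unit
        n_public = len(res_admin.links[land.clusters[0].id])
        assert all(len(s) == n_public for s in res_admin.links.values())


class TestRounding:
    def test_half_up_at_the_boundary(self):
        assert round_half_up(0.05, 1) == 0.1
        assert round_half_up(2.25, 1) == 2.3
        assert round_half_up(99.94999, 1) == 99.9
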