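"""Coordinate transforms: telescoping y-contiguity, z mid-plane
alignment, identity at age 18, DICOM reorientation, and agreement of the
vectorized pipeline with an independently coded scalar oracle."""

import numpy as np
import pytest

from agephantom.geometry_transform import (
    ScaledPhantom,
    TransformContext,
    phantom_height,
    reorient_to_dicom,
    reorient_to_phantom,
    scale_phantom,
    transform_x,
    transform_y,
    transform_z,
)
from agephantom.growth_scaling import continuous_factor, compute_factors
from agephantom.phantom_model import CHAIN_ORDER, BodyRegionId, Direction

VALIDATION_AGES = (0.1, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 10.0, 15.0, 18.0)


def oracle_transform(phantom, table, age, point, region):
    """Brute-force scalar re-derivation of the transform equations,
    straight from the region corner arrays (independent of
    TransformContext's cached offsets)."""
    x, y, z = point
    fx = continuous_factor(table, Direction.X, region, age)
    fy = continuous_factor(table, Direction.Y, region, age)
    fz = continuous_factor(table, Direction.Z, region, age)
    # x: plain product about the symmetry plane
    xt = x * fx
    # y: sum of fully scaled lengths of superior regions + in-region part
    yt = 0.0
    chain = list(CHAIN_ORDER)
    upto = chain.index(region) if region in chain else chain.index(
        BodyRegionId.TR)
    for rid in chain[:upto]:
        reg = phantom.regions[rid]
        l = reg.corners[:, 1].max() - reg.corners[:, 1].min()
        yt += l * continuous_factor(table, Direction.Y, rid, age)
    reg = phantom.region_for(region)
    yt += (y - reg.corners[:, 1].min()) * fy
    # z: offset from anterior boundary plus the head-centring shift
    uh = phantom.regions[BodyRegionId.UH]
    l_head_z = uh.corners[:, 2].max() - uh.corners[:, 2].min()
    f_head = continuous_factor(table, Direction.Z, BodyRegionId.UH, age)
    l_rz = reg.corners[:, 2].max() - reg.corners[:, 2].min()
    zshift = (l_head_z * f_head - l_rz * fz) / 2.0
    zt = (z - reg.corners[:, 2].min()) * fz + zshift
    return np.array([xt, yt, zt])


class TestScalarTransforms:
    def test_x_zero_fixed_point_and_sign(self, phantom, growth_table):
        ctx = TransformContext.create(phantom, growth_table, 2.0)
        assert transform_x(0.0, BodyRegionId.TR, ctx) == 0.0
        assert transform_x(-10.0, BodyRegionId.TR, ctx) < 0

    def test_x_identity_at_18(self, phantom, growth_table):
        ctx = TransformContext.create(phantom, growth_table, 18.0)
        for v in (-17.0, 0.0, 8.25):
            assert transform_x(v, BodyRegionId.TR, ctx) == v

    def test_y_top_of_head_maps_to_zero(self, phantom, growth_table):
        for age in (0.1, 3.9, 18.0):
            ctx = TransformContext.create(phantom, growth_table, age)
            assert transform_y(phantom.y_origin, BodyRegionId.UH, ctx) == 0.0

    def test_y_out_of_region_rejected(self, phantom, growth_table):
        ctx = TransformContext.create(phantom, growth_table, 5.0)
        with pytest.raises(ValueError, match="outside region"):
            transform_y(500.0, BodyRegionId.UH, ctx)

    def test_y_bottom_of_legs_at_18(self, phantom, growth_table):
        # at age 18, y_t at the legs' inferior boundary is the generic
        # stature (the 1 cm origin offset vanishes in the re-basing)
        ctx = TransformContext.create(phantom, growth_table, 18.0)
        y_bottom = phantom.regions[BodyRegionId.LG].y_ibr
        expected = sum(
            phantom.regions[r].l_y for r in CHAIN_ORDER
        )
        got = transform_y(y_bottom, BodyRegionId.LG, ctx)
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(y_bottom - phantom.y_origin, abs=1e-9)

    def test_z_anterior_boundary_maps_to_shift(self, phantom, growth_table):
        ctx = TransformContext.create(phantom, growth_table, 2.5)
        for rid in CHAIN_ORDER:
            z_a = ctx.z_abr[rid]
            assert transform_z(z_a, rid, ctx) == pytest.approx(
                ctx.z_shift[rid]
            )

    def test_z_shift_zero_for_reference_head(self, phantom, growth_table):
        # for uh the two shift terms cancel identically
        for age in (0.1, 7.3, 18.0):
            ctx = TransformContext.create(phantom, growth_table, age)
            assert ctx.z_shift[BodyRegionId.UH] == 0.0

    def test_z_shift_hand_value(self, phantom, growth_table):
        # hand evaluation: shift = (l_head,z * F_head - l_r,z * F_r) / 2
        ctx = TransformContext.create(phantom, growth_table, 1.0)
        rid = BodyRegionId.TR
        expected = (
            phantom.regions[BodyRegionId.UH].l_z
            * ctx.factors[(Direction.Z, BodyRegionId.UH)]
            - phantom.regions[rid].l_z * ctx.factors[(Direction.Z, rid)]
        ) / 2.0
        assert ctx.z_shift[rid] == expected


class TestScalePhantom:
    def test_identity_at_18_factors_and_extents(self, phantom, growth_table):
        sp = scale_phantom(phantom, growth_table, 18.0)
        assert all(f == 1.0 for f in sp.factors.factors.values())
        for rid in CHAIN_ORDER:
            g, s = phantom.regions[rid], sp.regions[rid]
            assert s.l_x == pytest.approx(g.l_x, abs=1e-12)
            assert s.l_y == pytest.approx(g.l_y, abs=1e-12)
            assert s.l_z == pytest.approx(g.l_z, abs=1e-12)

    def test_identity_at_18_organs_up_to_rebasing(self, phantom, growth_table):
        sp = scale_phantom(phantom, growth_table, 18.0)
        ctx = TransformContext.create(phantom, growth_table, 18.0)
        for g, s in zip(phantom.organs, sp.organs):
            shift = np.array([0.0, -phantom.y_origin,
                              ctx.z_shift[g.region]
                              - ctx.z_abr[g.region]])
            np.testing.assert_allclose(s.points, g.points + shift,
                                       atol=1e-9)

    @pytest.mark.parametrize("age", VALIDATION_AGES)
    def test_chain_contiguity(self, phantom, growth_table, age):
        sp = scale_phantom(phantom, growth_table, age)
        for a, b in zip(CHAIN_ORDER[:-1], CHAIN_ORDER[1:]):
            gap = abs(sp.regions[a].y_ibr - sp.regions[b].y_sbr)
            assert gap < 1e-9

    @pytest.mark.parametrize("age", VALIDATION_AGES)
    def test_z_midplane_alignment(self, phantom, growth_table, age):
        sp = scale_phantom(phantom, growth_table, age)
        f_head = sp.factors[(Direction.Z, BodyRegionId.UH)]
        target = phantom.regions[BodyRegionId.UH].l_z * f_head / 2.0
        for reg in sp.all_regions():
            mid = (reg.corners[:, 2].min() + reg.corners[:, 2].max()) / 2.0
            assert abs(mid - target) < 1e-9

    @pytest.mark.parametrize("age", (0.1, 1.0, 3.9, 12.4))
    def test_volume_scales_as_factor_product(self, phantom, growth_table, age):
        sp = scale_phantom(phantom, growth_table, age)
        for rid in CHAIN_ORDER:
            g = phantom.regions[rid]
            s = sp.regions[rid]
            prod = (sp.factors[(Direction.X, rid)]
                    * sp.factors[(Direction.Y, rid)]
                    * sp.factors[(Direction.Z, rid)])
            assert s.l_x * s.l_y * s.l_z == pytest.approx(
                g.l_x * g.l_y * g.l_z * prod, rel=1e-9
            )

    @pytest.mark.parametrize("age", (0.1, 2.0, 18.0))
    def test_organ_containment_preserved(self, phantom, growth_table, age):
        sp = scale_phantom(phantom, growth_table, age)
        for org in sp.organs:
            assert sp.region_for(org.region).contains(org.points).all(), \
                org.name

    def test_matches_oracle_pointwise(self, phantom, growth_table):
        for age in (0.1, 3.9, 10.0):
            sp = scale_phantom(phantom, growth_table, age)
            for g, s in zip(phantom.organs, sp.organs):
                expected = np.array([
                    oracle_transform(phantom, growth_table, age, p, g.region)
                    for p in g.points
                ])
                np.testing.assert_allclose(s.points, expected, atol=1e-9)

    def test_infant_height_and_head_fraction(self, phantom, growth_table):
        sp = scale_phantom(phantom, growth_table, 0.1)
        h = phantom_height(sp)
        head = (sp.regions[BodyRegionId.UH].l_y
                + sp.regions[BodyRegionId.LH].l_y)
        assert head / h == pytest.approx(0.25, abs=0.03)


class TestReorientation:
    def test_distances_preserved_times_ten(self, phantom, growth_table, rng):
        sp = scale_phantom(phantom, growth_table, 5.0)
        d = reorient_to_dicom(sp)
        a = sp.organs[0].points
        b = d.organs[0].points
        i, j = rng.integers(0, len(a), size=2)
        dist_cm = np.linalg.norm(a[i] - a[j])
        dist_mm = np.linalg.norm(b[i] - b[j])
        assert dist_mm == pytest.approx(10.0 * dist_cm, rel=1e-12)

    def test_round_trip_identity(self, phantom, growth_table):
        sp = scale_phantom(phantom, growth_table, 2.0)
        back = reorient_to_phantom(reorient_to_dicom(sp))
        for a, b in zip(sp.organs, back.organs):
            np.testing.assert_allclose(a.points, b.points, atol=1e-12)
        assert back.frame == "phantom"

    def test_head_at_largest_s(self, phantom, growth_table):
        sp = scale_phantom(phantom, growth_table, 5.0)
        d = reorient_to_dicom(sp)
        s_by_region = {
            rid: d.regions[rid].corners[:, 2].max() for rid in CHAIN_ORDER
        }
        assert s_by_region[BodyRegionId.UH] == max(s_by_region.values())

    def test_double_reorient_rejected(self, phantom, growth_table):
        d = reorient_to_dicom(scale_phantom(phantom, growth_table, 5.0))
        with pytest.raises(ValueError, match="already"):
            reorient_to_dicom(d)


class TestHeight:
    def test_height_at_18_is_generic_stature(self, phantom, growth_table):
        sp = scale_phantom(phantom, growth_table, 18.0)
        assert phantom_height(sp) == pytest.approx(phantom.total_height(),
                                                   abs=1e-9)

    @pytest.mark.parametrize("age", VALIDATION_AGES)
    def test_height_closed_form(self, phantom, growth_table, age):
        sp = scale_phantom(phantom, growth_table, age)
        closed = sum(
            phantom.regions[r].l_y * sp.factors[(Direction.Y, r)]
            for r in CHAIN_ORDER
        )
        assert phantom_height(sp) == pytest.approx(closed, abs=1e-9)

    def test_height_monotone_in_age(self, phantom, growth_table):
        ages = np.round(np.arange(1, 181, 3) / 10.0, 1)
        heights = [
            phantom_height(scale_phantom(phantom, growth_table, a))
            for a in ages
        ]
        assert np.all(np.diff(heights) >= -1e-9)

    def test_height_same_in_both_frames(self, phantom, growth_table):
        sp = scale_phantom(phantom, growth_table, 7.7)
        assert phantom_height(reorient_to_dicom(sp)) == pytest.approx(
            phantom_height(sp), rel=1e-12
        )
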