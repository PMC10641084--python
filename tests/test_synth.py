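"""Synthetic scene and phantom generator tests."""

import numpy as np
import pytest

from bpfscope.config import OpticalConfig
from bpfscope.optics import compute_psf, forward_image, make_pupil_grid, \
    pupil_function
from bpfscope.metrics import psf_fwhm
from bpfscope.synth import (
    BeadFieldSpec,
    SceneSpec,
    forward_multiplane,
    gen_bead_field,
    gen_multiplane_scene,
    gen_texture_scene,
    make_dataset,
)


class TestTextureScenes:
    def test_deterministic_under_seed(self):
        a = gen_texture_scene(SceneSpec(size=64, seed=5))
        b = gen_texture_scene(SceneSpec(size=64, seed=5))
        assert np.array_equal(a, b)

    def test_normalized_range(self):
        img = gen_texture_scene(SceneSpec(size=64, seed=9))
        assert img.min() == 0.0 and img.max() == 1.0

    def test_nondegenerate_variance(self):
        for seed in range(5):
            img = gen_texture_scene(SceneSpec(size=64, seed=seed))
            assert img.std() > 0.05

    def test_spectral_slope(self):
        """Radially averaged power spectrum follows the requested slope."""
        exponent = -1.5
        spec = SceneSpec(size=128, spectrum_exponent=exponent,
                         mix_texture=1.0, mix_blobs=0.0, mix_filaments=0.0,
                         smoothing_px=0.0)
        power = np.zeros((128, 128))
        for seed in range(50):
            s = SceneSpec(**{**spec.__dict__, "seed": seed})
            img = gen_texture_scene(s)
            power += np.abs(np.fft.fft2(img - img.mean())) ** 2
        fy = np.fft.fftfreq(128)[:, None]
        fx = np.fft.fftfreq(128)[None, :]
        f = np.hypot(fy, fx).ravel()
        p = power.ravel()
        # mid-frequency band, away from DC and Nyquist corners
        sel = (f > 0.04) & (f < 0.25)
        bins = np.linspace(0.04, 0.25, 12)
        idx = np.digitize(f[sel], bins)
        logf, logp = [], []
        for i in range(1, len(bins)):
            m = idx == i
            if m.sum() > 4:
                logf.append(np.log(np.mean(f[sel][m])))
                logp.append(np.log(np.mean(p[sel][m])))
        slope = np.polyfit(logf, logp, 1)[0]
        assert slope == pytest.approx(exponent, rel=0.10)


class TestBeadFields:
    def test_count_and_positions(self, fine_optics):
        spec = BeadFieldSpec(n_beads=4, size=256, seed=2)
        planes, table = gen_bead_field(spec, fine_optics)
        assert len(table) == 4
        img = planes[0.0]
        # each rendered peak lies within one pixel of the recorded position
        for _, row in table.iterrows():
            y, x = int(round(row.y_px)), int(round(row.x_px))
            win = img[y - 2:y + 3, x - 2:x + 3]
            assert win.max() == img[y - 2 + np.unravel_index(
                np.argmax(win), win.shape)[0],
                x - 2 + np.unravel_index(np.argmax(win), win.shape)[1]]
            py, px = np.unravel_index(np.argmax(win), win.shape)
            assert abs((y - 2 + py) - row.y_px) <= 1.0
            assert abs((x - 2 + px) - row.x_px) <= 1.0

    def test_minimum_separation(self, fine_optics):
        spec = BeadFieldSpec(n_beads=6, size=256, seed=4)
        planes, table = gen_bead_field(spec, fine_optics)
        pos = table[["y_px", "x_px"]].values
        fwhm_px = 0.51 * fine_optics.wavelength / fine_optics.na \
            / fine_optics.image_pitch
        for i in range(len(pos)):
            for j in range(i + 1, len(pos)):
                assert np.hypot(*(pos[i] - pos[j])) >= 3.0 * fwhm_px - 1e-9

    def test_overcrowding_rejected(self, fine_optics):
        with pytest.raises(ValueError):
            gen_bead_field(BeadFieldSpec(n_beads=500, size=128, seed=0),
                           fine_optics)

    def test_oversized_bead_rejected(self, fine_optics):
        with pytest.raises(ValueError):
            gen_bead_field(BeadFieldSpec(bead_diameter=1.0), fine_optics)

    def test_bead_image_fwhm_consistent_with_psf(self, fine_optics,
                                                 fine_grid):
        """Imaged-bead width matches the PSF broadened by the bead size."""
        spec = BeadFieldSpec(n_beads=3, size=256, seed=8)
        planes, table = gen_bead_field(spec, fine_optics)
        pupil = pupil_function(np.zeros_like(fine_grid.rho), fine_grid)
        psf = compute_psf(pupil, 0.0, fine_grid)
        img = forward_image(planes[0.0], psf, sigma=0.0)
        measured = []
        for _, row in table.iterrows():
            y, x = int(round(row.y_px)), int(round(row.x_px))
            win = img[y - 16:y + 17, x - 16:x + 17]
            measured.append(psf_fwhm(win, fine_optics.image_pitch))
        # prediction: PSF convolved with the bead's own profile
        bead_img = forward_image(planes[0.0], psf, sigma=0.0)
        sigma_bead = spec.bead_diameter / 2.3548
        predicted = np.sqrt(psf_fwhm(psf, fine_optics.image_pitch) ** 2
                            + spec.bead_diameter**2)
        assert np.mean(measured) == pytest.approx(predicted, rel=0.03)


class TestMultiplane:
    def test_single_plane_degenerates_to_forward_image(self, paper_optics):
        scene = gen_texture_scene(SceneSpec(size=64, seed=3))
        grid = make_pupil_grid(paper_optics)
        phase = np.zeros_like(grid.rho)
        stack = forward_multiplane([(scene, 1.5)], phase, paper_optics,
                                   sigma=0.0)
        pupil = pupil_function(phase, grid)
        from bpfscope.optics import z_to_psi

        psf = compute_psf(pupil, float(z_to_psi(1.5, paper_optics)), grid)
        direct = forward_image(scene, psf, sigma=0.0)
        assert np.allclose(stack, direct, atol=1e-12)

    def test_symmetric_planes_binary_pupil(self, paper_optics):
        """Two identical planes at +-z contribute identically (real pupil)."""
        scene = gen_texture_scene(SceneSpec(size=64, seed=6))
        grid = make_pupil_grid(paper_optics)
        binary = np.where(grid.rho > 0.7, np.pi, 0.0) * grid.circ_mask
        up = forward_multiplane([(scene, 2.0)], binary, paper_optics,
                                sigma=0.0, normalize=False)
        down = forward_multiplane([(scene, -2.0)], binary, paper_optics,
                                  sigma=0.0, normalize=False)
        assert np.allclose(up, down, atol=1e-8)

    def test_energy_additive(self, paper_optics):
        s1 = gen_texture_scene(SceneSpec(size=64, seed=1))
        s2 = gen_texture_scene(SceneSpec(size=64, seed=2))
        phase = np.zeros((64, 64))
        both = forward_multiplane([(s1, 0.0), (s2, 3.0)], phase,
                                  paper_optics, sigma=0.0, normalize=False)
        p1 = forward_multiplane([(s1, 0.0)], phase, paper_optics,
                                sigma=0.0, normalize=False)
        p2 = forward_multiplane([(s2, 3.0)], phase, paper_optics,
                                sigma=0.0, normalize=False)
        assert both.sum() == pytest.approx(p1.sum() + p2.sum(), rel=1e-9)

    def test_distinct_z_required(self):
        with pytest.raises(ValueError):
            gen_multiplane_scene([(SceneSpec(seed=0), 1.0),
                                  (SceneSpec(seed=1), 1.0)])


class TestMakeDataset:
    def test_manifest_reproducible(self, tmp_path):
        m1 = make_dataset(4, 2, 2, SceneSpec(size=32), 7, tmp_path / "a")
        m2 = make_dataset(4, 2, 2, SceneSpec(size=32), 7, tmp_path / "b")
        assert m1.drop(columns="file").equals(m2.drop(columns="file"))
        csv_a = (tmp_path / "a" / "manifest.csv").read_text()
        csv_b = (tmp_path / "b" / "manifest.csv").read_text()
        assert csv_a == csv_b

    def test_split_counts_and_augmentation(self, tmp_path):
        m = make_dataset(6, 3, 2, SceneSpec(size=32), 1, tmp_path / "d")
        assert (m.split == "train").sum() == 6
        assert (m.split == "val").sum() == 3
        assert (m.split == "test").sum() == 2
        assert (m.loc[m.split != "train", "augmentation"] == "none").all()

    def test_images_on_disk_match_seeds(self, tmp_path):
        import tifffile

        m = make_dataset(0, 0, 3, SceneSpec(size=32), 5, tmp_path / "e")
        row = m.iloc[1]
        img = tifffile.imread(tmp_path / "e" / row.file)
        regen = gen_texture_scene(SceneSpec(size=32, seed=int(row.seed)))
        assert np.allclose(img, regen.astype(np.float32), atol=1e-7)
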