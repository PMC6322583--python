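import numpy as np
import pytest

from pcmorph.images import IntensityImage, LabelImage
from pcmorph.synthcell import CellShapeSpec, MosaicSpec, generate_mosaic


@pytest.fixture(scope="session")
def noiseless_mosaic():
    """2x2 noiseless mosaic of lobed cells with full ground truth."""
    spec = MosaicSpec(
        cells=tuple(
            CellShapeSpec(seed=i, lobe_count_true=6, lobe_amplitude=0.35)
            for i in range(4)
        ),
        grid_shape=(2, 2),
        noise_sd=0.0,
        seed=11,
    )
    wall, outline, labels, truth = generate_mosaic(spec)
    return {
        "spec": spec,
        "wall": wall,
        "outline": outline,
        "labels": labels,
        "truth": truth,
    }


@pytest.fixture()
def disk_label_image():
    """Rasterized filled disk, radius 100 px at 0.5 um/px."""
    from skimage.draw import disk

    mask = np.zeros((260, 260), dtype=np.int32)
    rr, cc = disk((130, 130), 100.5)
    mask[rr, cc] = 1
    return LabelImage(mask, 0.5)


def toy_two_region_labels():
    """20x20 label image: two 8x20 regions separated by a 4-px wall band."""
    lab = np.zeros((20, 20), dtype=np.int32)
    lab[0:8, :] = 1
    lab[12:20, :] = 2
    return lab


@pytest.fixture()
def ramp_wall_toy():
    """The toy two-region image with an intensity ramp over the wall band."""
    lab = toy_two_region_labels()
    sig = np.zeros((20, 20), dtype=float)
    ramp = np.arange(20 * 4, dtype=float).reshape(4, 20)
    sig[8:12, :] = ramp
    return LabelImage(lab, 1.0), IntensityImage(sig, 1.0)
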