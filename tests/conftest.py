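import numpy as np
import pytest

import isletquant as iq


@pytest.fixture(scope="session")
def rich_section():
    """Default PP-rich preset (seed 1): stack + ground truth."""
    return iq.generate_section(iq.pp_rich_config())


@pytest.fixture(scope="session")
def poor_section():
    """Default PP-poor preset (seed 1): stack + ground truth."""
    return iq.generate_section(iq.pp_poor_config())


@pytest.fixture(scope="session")
def rich_masks(rich_section):
    stack, _ = rich_section
    return iq.segment_channels(stack)


@pytest.fixture(scope="session")
def poor_masks(poor_section):
    stack, _ = poor_section
    return iq.segment_channels(stack)


@pytest.fixture(scope="session")
def rich_objects(rich_masks):
    return iq.detect_objects(rich_masks)


@pytest.fixture(scope="session")
def poor_objects(poor_masks):
    return iq.detect_objects(poor_masks)


def truth_maskset(truth):
    """Exact MaskSet built from generator ground truth (no segmentation)."""
    from isletquant.synthetic import TYPE_CODES

    masks = {t: truth.type_map == code for t, code in TYPE_CODES.items()}
    tissue = np.ones_like(truth.type_map, dtype=bool)
    record = {t: {"method": "ground_truth", "threshold": 0.5, "warnings": []} for t in masks}
    return iq.MaskSet(
        masks=masks,
        tissue_mask=tissue,
        threshold_record=record,
        pixel_size=truth.config.pixel_size,
    )
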