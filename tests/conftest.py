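import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dermamesh import FieldSpec, generate_volume

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


SPHERE_CENTER = (3.1, 3.1, 3.1)
SPHERE_RADIUS = 2.05
SPACING = (0.2, 0.2, 0.2)

TORUS_CENTER = (3.9, 3.9, 2.3)
TORUS_RING = 1.8
TORUS_TUBE = 0.85


@pytest.fixture(scope="session")
def sphere_volume():
    """Signed-distance sphere, positive inside, on a 32^3 grid (h = 0.2)."""
    return generate_volume(
        FieldSpec(kind="sphere", center=SPHERE_CENTER, radius=SPHERE_RADIUS),
        (32, 32, 32),
        spacing=SPACING,
    )


@pytest.fixture(scope="session")
def torus_volume():
    """Signed-distance torus (axis along z) on a 40x40x24 grid (h = 0.2)."""
    return generate_volume(
        FieldSpec(kind="torus", center=TORUS_CENTER, ring_radius=TORUS_RING, tube_radius=TORUS_TUBE),
        (40, 40, 24),
        spacing=SPACING,
    )


@pytest.fixture(scope="session")
def noise_volume():
    """Seeded band-limited Gaussian field on a 24^3 grid."""
    return generate_volume(FieldSpec(kind="smooth_noise", seed=7, smoothing=2.0), (24, 24, 24))


def write_dicom_slice(
    path,
    pixels,
    *,
    instance_number=None,
    position=None,
    pixel_spacing=(1.0, 1.0),
    slope=None,
    intercept=None,
):
    """Write one synthetic single-frame grayscale DICOM slice.

    Deliberately carries fake patient-identifying metadata so tests can
    confirm none of it survives volume assembly.
    """
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    pixels = np.asarray(pixels, dtype="<u2")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.PatientName = "Synthetic^Fixture"
    ds.PatientID = "SYNTH-0001"
    ds.PatientBirthDate = "19700101"
    ds.StudyDate = "20200101"
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelSpacing = [pixel_spacing[0], pixel_spacing[1]]
    if instance_number is not None:
        ds.InstanceNumber = instance_number
    if position is not None:
        ds.ImagePositionPatient = list(position)
    if slope is not None:
        ds.RescaleSlope = slope
    if intercept is not None:
        ds.RescaleIntercept = intercept
    ds.PixelData = pixels.tobytes()
    pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
    return path
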