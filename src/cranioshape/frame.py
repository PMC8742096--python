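"""Anatomical coordinate frame from the three cranial landmarks.

The frame follows the clinical registration convention used by cap-based
head scanners: the origin is the midpoint between the two preauricular
points; +X points anteriorly toward the glabella (the point between the
eyes); +Y is the component of the right-to-left inter-preauricular vector
orthogonal to X, so +Y is the patient's left; +Z = X x Y completes a
right-handed frame and points toward the vertex.

All transforms are rigid (rotation + translation); models stay in true mm.
"""

from __future__ import annotations

import numpy as np

from .errors import GeometryError
from .model_io import HeadModel, Landmarks

#: Minimum landmark-triangle area (mm^2) below which the frame is undefined.
MIN_TRIANGLE_AREA_MM2 = 1.0


def landmark_frame(landmarks: Landmarks) -> tuple[np.ndarray, np.ndarray]:
    """Rotation ``R`` (world->anatomical, rows are the axes) and origin.

    A point ``p`` in scanner coordinates maps to ``R @ (p - origin)``.

    Raises
    ------
    GeometryError
        If the landmarks are collinear (glabella on the inter-preauricular
        axis) or coincident.
    """
    pa_l = np.asarray(landmarks.preauricular_left, dtype=float)
    pa_r = np.asarray(landmarks.preauricular_right, dtype=float)
    gl = np.asarray(landmarks.glabella, dtype=float)

    origin = 0.5 * (pa_l + pa_r)
    x = gl - origin
    nx = np.linalg.norm(x)
    if nx == 0.0:
        raise GeometryError("glabella coincides with the inter-preauricular midpoint")
    x_hat = x / nx

    # Exact orthogonal projection of the inter-preauricular vector onto the
    # plane normal to X: for two points this minimises their summed squared
    # distance to the Y axis in closed form.
    d = pa_l - pa_r
    y = d - (d @ x_hat) * x_hat
    ny = np.linalg.norm(y)
    area = 0.5 * np.linalg.norm(np.cross(pa_l - gl, pa_r - gl))
    if area <= MIN_TRIANGLE_AREA_MM2 or ny == 0.0:
        raise GeometryError(
            f"landmarks are collinear or nearly so (triangle area {area:.3g} mm^2)"
        )
    y_hat = y / ny
    z_hat = np.cross(x_hat, y_hat)
    R = np.vstack([x_hat, y_hat, z_hat])
    return R, origin


def align_head(model: HeadModel) -> HeadModel:
    """Register a head point cloud into its anatomical landmark frame.

    Returns a new :class:`HeadModel` with ``is_aligned=True`` whose landmarks
    have been transformed consistently: the glabella lies on +X, the
    preauricular points have opposite y of equal magnitude and z = 0.
    Idempotent up to floating-point error.
    """
    if model.landmarks is None:
        raise GeometryError("head model has no landmarks; cannot align")
    R, origin = landmark_frame(model.landmarks)
    pts = (np.asarray(model.points, dtype=float) - origin) @ R.T
    lm = Landmarks(
        preauricular_left=R @ (np.asarray(model.landmarks.preauricular_left, float) - origin),
        preauricular_right=R @ (np.asarray(model.landmarks.preauricular_right, float) - origin),
        glabella=R @ (np.asarray(model.landmarks.glabella, float) - origin),
    )
    return HeadModel(id=model.id, points=pts, landmarks=lm, is_aligned=True)
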