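"""Clip mesh triangles against an implicit region (marching-triangles style).

Shared by the sphere cropper (exact edge-sphere intersections) and the
contact-patch detector (linear interpolation of a per-vertex distance field).
Faces fully inside are kept, faces fully outside dropped, and crossing faces
are cut along the boundary, with cut points cached per directed edge so that
adjacent faces share identical boundary vertices.
"""

from __future__ import annotations

from typing import Callable

import numpy as np


def clip_triangles(
    vertices: np.ndarray,
    faces: np.ndarray,
    inside: np.ndarray,
    isect: Callable[[int, int], np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Clip ``faces`` to the region where ``inside`` holds.

    Parameters
    ----------
    vertices, faces : the source mesh
    inside : bool per vertex
    isect : ``isect(i_in, i_out)`` returns the boundary point on the segment
        from inside vertex ``i_in`` to outside vertex ``i_out``

    Returns
    -------
    (all_vertices, new_faces, src_face) where ``all_vertices`` stacks the
    original vertices with any cut points, ``new_faces`` indexes into it with
    winding preserved, and ``src_face[i]`` is the source-face index that
    output face ``i`` came from.
    """
    faces = np.asarray(faces, dtype=np.int64)
    if not len(faces):
        return np.asarray(vertices, float).reshape(-1, 3), faces.reshape(-1, 3), np.empty(0, np.int64)
    tri_in = inside[faces]
    n_in = tri_in.sum(axis=1)

    out_faces: list[tuple[int, int, int]] = []
    src: list[int] = []
    for fi in np.nonzero(n_in == 3)[0]:
        out_faces.append(tuple(faces[fi]))
        src.append(int(fi))

    extra: list[np.ndarray] = []
    cache: dict[tuple[int, int], int] = {}
    nv = len(vertices)

    def cut(i_in: int, i_out: int) -> int:
        nonlocal nv
        key = (int(i_in), int(i_out))
        if key not in cache:
            extra.append(np.asarray(isect(int(i_in), int(i_out)), dtype=float))
            cache[key] = nv
            nv += 1
        return cache[key]

    for fi in np.nonzero((n_in == 1) | (n_in == 2))[0]:
        f = faces[fi]
        m = tri_in[fi]
        if n_in[fi] == 1:
            r = int(np.nonzero(m)[0][0])
            a, b, c = int(f[r]), int(f[(r + 1) % 3]), int(f[(r + 2) % 3])
            out_faces.append((a, cut(a, b), cut(a, c)))
            src.append(int(fi))
        else:
            r = int(np.nonzero(~m)[0][0])  # the single outside vertex
            c, a, b = int(f[r]), int(f[(r + 1) % 3]), int(f[(r + 2) % 3])
            qbc, qca = cut(b, c), cut(a, c)
            out_faces.append((a, b, qbc))
            src.append(int(fi))
            out_faces.append((a, qbc, qca))
            src.append(int(fi))

    all_vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    if extra:
        all_vertices = np.vstack([all_vertices, np.array(extra)])
    return all_vertices, np.array(out_faces, dtype=np.int64).reshape(-1, 3), np.array(src, dtype=np.int64)


def compact_mesh(vertices: np.ndarray, faces: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop vertices not referenced by any face and reindex faces."""
    if not len(faces):
        return np.empty((0, 3)), np.empty((0, 3), dtype=np.int64)
    used = np.unique(faces)
    remap = np.full(len(vertices), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    return vertices[used], remap[faces]
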