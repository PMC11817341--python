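"""Linear (P1) tetrahedral finite-element operators.

Assembles the operators needed by the transient diffusion/conduction
solver: lumped mass vectors, coefficient-weighted stiffness matrices and
lumped boundary-face integrals.  Mass lumping keeps the discrete maximum
principle for the steep moisture fronts near the evaporating surface.

The sparsity pattern is fixed per mesh, so repeated assemblies scatter
element contributions straight into CSR data arrays; the linear systems
(symmetric positive definite) are solved by conjugate gradients
preconditioned with a cached LU factorization that is refreshed only
when the iteration stalls.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import LinearOperator, cg, spilu, splu

from .geometry import Mesh

__all__ = ["P1Operators", "CachedSPDSolver"]


class P1Operators:
    """Precomputed element geometry and assembly helpers for one mesh."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        nodes, tets = mesh.nodes, mesh.tets
        p = nodes[tets]  # (m, 4, 3)
        # Jacobian columns are edge vectors from vertex 0
        J = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]],
                     axis=2)  # (m, 3, 3)
        detJ = np.linalg.det(J)
        if np.any(detJ <= 0):
            raise ValueError("mesh contains non-positively oriented tetrahedra")
        self.volumes = detJ / 6.0
        Jinv = np.linalg.inv(J)
        # gradients of the four barycentric basis functions
        g_ref = np.array([[-1.0, -1.0, -1.0],
                          [1.0, 0.0, 0.0],
                          [0.0, 1.0, 0.0],
                          [0.0, 0.0, 1.0]])
        self.grads = np.einsum("ik,mkl->mil", g_ref, Jinv)  # (m, 4, 3)
        # geometric local stiffness: V_e * grad_i . grad_j
        self._local_stiff = np.einsum(
            "mil,mjl,m->mij", self.grads, self.grads, self.volumes
        )
        self.n = mesh.n_nodes

        # fixed CSR sparsity pattern + scatter map for fast reassembly
        rows = np.repeat(tets, 4, axis=1).reshape(-1)
        cols = np.tile(tets, (1, 4)).reshape(-1)
        order = np.lexsort((cols, rows))
        r_s, c_s = rows[order], cols[order]
        new = np.concatenate([[True],
                              (r_s[1:] != r_s[:-1]) | (c_s[1:] != c_s[:-1])])
        grp = np.cumsum(new) - 1
        self._entry_group = np.empty(len(rows), dtype=np.int64)
        self._entry_group[order] = grp
        self._nnz = int(grp[-1]) + 1
        self._csr_indices = c_s[new].astype(np.int32)
        counts = np.bincount(r_s[new], minlength=self.n)
        self._csr_indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int32)
        # positions of diagonal entries in the CSR data array
        diag_rows = np.arange(self.n)
        self._diag_pos = np.empty(self.n, dtype=np.int64)
        for_diag = (r_s[new] == c_s[new])
        self._diag_pos[r_s[new][for_diag]] = np.flatnonzero(for_diag)

        # lumped volume per node (consistent with a lumped mass matrix)
        self.lumped_volume = np.zeros(self.n)
        np.add.at(self.lumped_volume, tets.ravel(),
                  np.repeat(self.volumes / 4.0, 4))

        # lumped boundary area per node over the active faces
        self.node_area = mesh.node_boundary_area(active_only=True)
        self.surface_nodes = np.flatnonzero(self.node_area > 0)
        self.total_active_area = float(self.node_area.sum())

    def stiffness_data(self, kappa_elem=None) -> np.ndarray:
        """CSR data array of the stiffness matrix with an optional
        per-element coefficient."""
        local = self._local_stiff
        if kappa_elem is not None:
            local = local * np.asarray(kappa_elem)[:, None, None]
        return np.bincount(self._entry_group, weights=local.reshape(-1),
                           minlength=self._nnz)

    def matrix(self, stiff_data: np.ndarray, diag: np.ndarray | None = None
               ) -> sparse.csr_matrix:
        """CSR matrix from stiffness data plus an optional added
        diagonal (mass and Robin terms)."""
        data = stiff_data.copy()
        if diag is not None:
            data[self._diag_pos] += diag
        return sparse.csr_matrix((data, self._csr_indices, self._csr_indptr),
                                 shape=(self.n, self.n))

    def stiffness(self, kappa_elem=None) -> sparse.csr_matrix:
        """Assembled stiffness matrix (convenience wrapper)."""
        return self.matrix(self.stiffness_data(kappa_elem))

    def element_mean(self, nodal: np.ndarray) -> np.ndarray:
        """Mean of a nodal field over each element's vertices."""
        return nodal[self.mesh.tets].mean(axis=1)

    def volume_average(self, nodal: np.ndarray) -> float:
        return float(self.lumped_volume @ nodal / self.lumped_volume.sum())


class CachedSPDSolver:
    """Solve a slowly-varying SPD system by preconditioned CG.

    The Jacobi-scaled system is preconditioned with a cached incomplete
    (or, for stiffness-dominated systems, exact) LU factorization that is
    refreshed whenever CG needs more than `refresh_iters` iterations --
    i.e. only when the matrix has drifted far from the factorized one.
    If an incomplete factorization proves inadequate for the matrix
    family, the solver permanently switches itself to exact
    factorizations.
    """

    def __init__(self, refresh_iters: int = 15, rtol: float = 1e-7,
                 factorization: str = "ilu"):
        self._lu = None
        self.refresh_iters = refresh_iters
        self.rtol = rtol
        if factorization not in ("ilu", "lu"):
            raise ValueError("factorization must be 'ilu' or 'lu'")
        self.factorization = factorization

    def _refactor(self, As: sparse.csc_matrix):
        if self.factorization == "ilu":
            self._lu = spilu(As, drop_tol=1e-3, fill_factor=10)
        else:
            self._lu = splu(As)

    def solve(self, A: sparse.csr_matrix, b: np.ndarray,
              x0: np.ndarray | None = None) -> np.ndarray:
        # symmetric diagonal (Jacobi) scaling equilibrates the system --
        # mass, stiffness and Robin contributions span several decades --
        # and keeps the incomplete factorization stable
        d = np.sqrt(A.diagonal())
        dinv = 1.0 / d
        Dinv = sparse.diags(dinv)
        As = (Dinv @ A @ Dinv).tocsc()
        bs = b * dinv
        x0s = x0 * d if x0 is not None else None
        if self._lu is None:
            self._refactor(As)
        M = LinearOperator(As.shape, self._lu.solve)
        xs, info = cg(As, bs, x0=x0s, M=M, rtol=self.rtol, atol=0.0,
                      maxiter=self.refresh_iters)
        if info != 0:
            self._refactor(As)
            xs, info = cg(As, bs, x0=xs,
                          M=LinearOperator(As.shape, self._lu.solve),
                          rtol=self.rtol, atol=0.0, maxiter=500)
            if info != 0:
                # incomplete factorization inadequate for this matrix
                # family: fall back to (and keep) exact factorizations
                self.factorization = "lu"
                self._refactor(As)
                xs = self._lu.solve(bs)
        return xs * dinv
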