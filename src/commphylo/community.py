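"""Sites x species presence/absence matrices ordered along a gradient.

The container couples a binary occurrence table (rows = sites in strictly
increasing elevation order, columns = species) with per-site elevations.
Besides I/O and summaries it implements single-gap elevational interpolation:
a species absent from exactly one site that is recorded at both the
immediately adjacent lower and higher sites is treated as present there,
on the grounds that the species' elevational range is plausibly continuous.
Runs of two or more consecutive absences are never filled, and terminal
absences (below the lowest or above the highest record) are never filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import LookupError_, ValidationError

__all__ = ["CommunityMatrix", "MatrixSummary", "read_matrix"]

INTERPOLATION_MODES = ("strict-single", "any-flanked", "off")


@dataclass(frozen=True)
class MatrixSummary:
    """Occurrence summary: per-site richness, species and occurrence totals."""

    richness: pd.Series  # per-site row sums, index = site labels
    n_species: int
    n_occurrences: int


class CommunityMatrix:
    """Binary sites x species matrix with ordered site elevations.

    Parameters
    ----------
    presence:
        DataFrame with site labels as index and species labels as columns;
        entries must be 0/1.
    elevations:
        Per-site elevations (m a.s.l.), strictly increasing in row order.
        If omitted, site labels must themselves parse as numbers and are
        used as elevations.
    """

    def __init__(self, presence: pd.DataFrame, elevations=None):
        presence = presence.copy()
        presence.index = presence.index.map(str)
        presence.columns = presence.columns.map(str)
        if presence.index.duplicated().any():
            raise ValidationError("duplicate site labels")
        if presence.columns.duplicated().any():
            raise ValidationError("duplicate species labels")
        values = presence.to_numpy()
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            cells = [
                f"({presence.index[i]}, {presence.columns[j]})={values[i, j]!r}"
                for i, j in zip(*np.nonzero(bad))
            ][:10]
            raise ValidationError(f"non-binary entries at: {', '.join(cells)}")
        self.presence = presence.astype(np.int8)
        if elevations is None:
            try:
                elevations = [float(s) for s in presence.index]
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    "site labels are not numeric; pass elevations explicitly"
                ) from exc
        elev = pd.Series(np.asarray(elevations, dtype=float), index=presence.index, name="elevation")
        if len(elev) != len(presence.index):
            raise ValidationError("one elevation per site required")
        if not np.all(np.diff(elev.to_numpy()) > 0):
            raise ValidationError("site elevations must be strictly increasing")
        self.elevations = elev

    # ------------------------------------------------------------------ #

    @property
    def sites(self) -> list[str]:
        return [str(s) for s in self.presence.index]

    @property
    def species(self) -> list[str]:
        return [str(s) for s in self.presence.columns]

    @property
    def n_sites(self) -> int:
        return self.presence.shape[0]

    @property
    def n_species(self) -> int:
        return self.presence.shape[1]

    def species_at(self, site) -> list[str]:
        """Species recorded as present at one site."""
        if site not in self.presence.index:
            raise LookupError_(f"unknown site {site!r}")
        row = self.presence.loc[site]
        return [str(s) for s in row.index[row == 1]]

    def summarize(self) -> MatrixSummary:
        """Per-site richness, species count and total occurrences."""
        richness = self.presence.sum(axis=1)
        richness.name = "richness"
        return MatrixSummary(
            richness=richness,
            n_species=int(self.presence.shape[1]),
            n_occurrences=int(self.presence.to_numpy().sum()),
        )

    # ------------------------------------------------------------------ #

    def interpolate_single_gaps(self, mode: str = "strict-single") -> "CommunityMatrix":
        """Fill internal absence gaps in each species' elevational range.

        ``strict-single`` fills only absence runs of length exactly one that
        are flanked by presences at both adjacent sites. ``any-flanked``
        fills every internal absence between the lowest and highest record
        of the species (a looser reading). ``off`` returns a copy unchanged.
        Idempotent in every mode; never removes a presence.
        """
        if mode not in INTERPOLATION_MODES:
            raise ValueError(f"mode must be one of {INTERPOLATION_MODES}")
        values = self.presence.to_numpy().copy()
        if mode == "off" or values.shape[0] < 3:
            return CommunityMatrix(
                pd.DataFrame(values, index=self.presence.index, columns=self.presence.columns),
                self.elevations.to_numpy(),
            )
        if mode == "strict-single":
            interior = values[1:-1]
            fill = (interior == 0) & (values[:-2] == 1) & (values[2:] == 1)
            interior[fill] = 1
        else:  # any-flanked
            for j in range(values.shape[1]):
                col = values[:, j]
                hits = np.nonzero(col)[0]
                if hits.size >= 2:
                    col[hits[0]: hits[-1] + 1] = 1
        return CommunityMatrix(
            pd.DataFrame(values, index=self.presence.index, columns=self.presence.columns),
            self.elevations.to_numpy(),
        )

    # -- I/O ------------------------------------------------------------ #

    def to_csv(self, path) -> None:
        self.presence.to_csv(path)

    def __repr__(self) -> str:  # pragma: no cover
        s = self.summarize()
        return (
            f"<CommunityMatrix: {self.n_sites} sites x {self.n_species} species, "
            f"{s.n_occurrences} occurrences>"
        )


def read_matrix(path, orientation: str = "sites-rows", elevations=None) -> CommunityMatrix:
    """Read a binary occurrence CSV.

    The first column holds row labels; ``orientation`` declares whether rows
    are sites (default) or species. Species recorded nowhere are rejected.
    """
    if orientation not in ("sites-rows", "species-rows"):
        raise ValueError("orientation must be 'sites-rows' or 'species-rows'")
    df = pd.read_csv(path, index_col=0)
    if orientation == "species-rows":
        df = df.T
    matrix = CommunityMatrix(df, elevations=elevations)
    empty = [sp for sp, tot in matrix.presence.sum(axis=0).items() if tot == 0]
    if empty:
        raise ValidationError(f"species with no occurrences: {empty[:10]}")
    return matrix
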