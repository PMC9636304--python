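"""Access to the applied datasets the package is demonstrated on.

The cognition rating data (194 children rated 1..7 on six self-regulation
items, the cognitive domain of a multi-facet generalizability study) are
distributed inside the R package ``MPsychoR`` on CRAN and are not bundled
here.  A one-time export produces the CSV this loader expects::

    Rscript -e 'library(MPsychoR); data(Lakes);
                cg <- subset(Lakes, subtest == "cognitive");
                w <- reshape(cg[, c("personID", "item", "score")],
                             idvar = "personID", timevar = "item",
                             direction = "wide");
                write.csv(w[, -1], "cognition.csv", row.names = FALSE)'

Column order must follow the item numbering; values are the raw 1..7
ratings.  :func:`load_cognition` returns them shifted to 0..6, ready for a
seven-category ordinal model, or unshifted for the continuous
approximation used with linear difficulty functions.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["load_cognition", "DEFAULT_COGNITION_PATH"]

DEFAULT_COGNITION_PATH = Path("data") / "cognition.csv"


def load_cognition(path=None, shift: bool = False) -> pd.DataFrame:
    """Load the six-item cognition ratings from a user-supplied CSV.

    Parameters
    ----------
    path : path-like, optional
        Location of the exported CSV (default ``data/cognition.csv``
        relative to the working directory).
    shift : bool
        If true, shift the 1..7 ratings to 0..6.

    Raises
    ------
    FileNotFoundError
        With export instructions, when the file is absent.
    """
    path = Path(path) if path is not None else DEFAULT_COGNITION_PATH
    if not path.exists():
        raise FileNotFoundError(
            f"cognition data not found at {path}; export it from the CRAN "
            "package MPsychoR (see irthresh.datasets module docstring) and "
            "place the CSV there")
    df = pd.read_csv(path)
    df.columns = [f"item{i}" for i in range(1, len(df.columns) + 1)]
    if df.shape[1] != 6:
        raise ValueError(f"expected 6 items, found {df.shape[1]}")
    if shift:
        df = df - 1
    return df
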