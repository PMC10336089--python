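"""Demo: gradient-boosted regression on persistent Dirac features.

Expects a directory of SDF structures and a CSV with columns (name, target),
e.g. experimental hydration free energies in kcal/mol.  Thin wiring around
xgboost with the reference hyperparameters; not part of the tested core.

Usage: python examples/solvation_xgboost.py SDF_DIR targets.csv
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from xgboost import XGBRegressor

from pdirac import featurize_table, freesolv_config, read_structure


def main(sdf_dir: str, targets_csv: str) -> None:
    targets = pd.read_csv(targets_csv).set_index("name")["target"]
    mols = [read_structure(f) for f in sorted(Path(sdf_dir).glob("*.sdf"))]
    table = featurize_table(mols, freesolv_config()).set_index("name")
    X = table.to_numpy()
    y = targets.loc[table.index].to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(X, y, test_size=0.1, random_state=0)
    model = XGBRegressor(
        n_estimators=20000, learning_rate=0.1, max_depth=7,
        subsample=0.4, colsample_bytree=0.8,
    )
    model.fit(X_tr, y_tr)
    rmse = float(np.sqrt(np.mean((model.predict(X_te) - y_te) ** 2)))
    print(f"test RMSE: {rmse:.3f}")


if __name__ == "__main__":
    main(sys.argv[1], sys.argv[2])
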