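"""Rerun the three result stages on a user-supplied otolith-chemistry table.

The published per-fish data deposit (element:Ca ratios and stable isotopes of
nuclear and marginal otolith regions) is not bundled with this package.  If
you have downloaded it, reshape it into the signature-table layout
(columns: fish_id, region in {nuclear, marginal}, one column per element,
d18O, d13C) and point this script at it; optionally add a transect table
(fish_id, index, distance, element columns) to rerun habitat-shift detection.

Usage:
    python scripts/reanalyze_deposit.py --signatures signatures.csv \
        [--transects transects.csv] [--seed 1] [--out-dir deposit_out]
"""

from __future__ import annotations

import argparse
import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from otogeo import io as oio  # noqa: E402
from otogeo.changepoint import cohort_shift_summary, transect_shift  # noqa: E402
from otogeo.mixture import bic_select, prepare_signatures  # noqa: E402
from otogeo.ontogeny import mahalanobis_gram, paired_contrast, permanova  # noqa: E402
from otogeo.preprocess import GrowthModel  # noqa: E402


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--signatures", type=pathlib.Path, required=True)
    parser.add_argument("--transects", type=pathlib.Path, default=None)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=pathlib.Path, default=pathlib.Path("deposit_out"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    sigs = oio.read_signatures(args.signatures)
    elements = sorted({e for s in sigs for e in s.elemental})
    nuc = oio.signatures_frame(sigs, "nuclear", elements, isotopes=True)
    marg = oio.signatures_frame(sigs, "marginal", elements, isotopes=True)
    common = nuc.index.intersection(marg.index)
    nuc, marg = nuc.loc[common], marg.loc[common]

    # stage one: juvenile-vs-adult contrasts and multivariate separation
    rows = []
    for var in elements + ["d18O", "d13C"]:
        try:
            rows.append(vars(paired_contrast(nuc[var].to_numpy(), marg[var].to_numpy(),
                                             variable=var)))
        except ValueError:
            continue
    pd.DataFrame(rows).to_csv(args.out_dir / "stage_contrasts.csv", index=False)

    mask = np.concatenate([nuc[elements].notna().all(1), marg[elements].notna().all(1)])
    X = np.vstack([nuc[elements].to_numpy(), marg[elements].to_numpy()])[mask]
    labels = np.array(["nuclear"] * len(nuc) + ["marginal"] * len(marg))[mask]
    fish_ids = np.concatenate([common, common])[mask]
    res = permanova(mahalanobis_gram(X), labels, within=fish_ids,
                    n_perm=9999, seed=args.seed)
    (args.out_dir / "permanova.json").write_text(json.dumps(vars(res), indent=2))
    print(f"PERMANOVA: pseudo-F = {res.pseudo_F:.3f}, p = {res.p_value:.4f}")

    # stage two: number and mixing of nursery sources
    for kind, frame in (("elemental", nuc[elements].dropna()),
                        ("isotopic", nuc[["d18O", "d13C"]].dropna())):
        if len(frame) < 10:
            continue
        Z, names = prepare_signatures(frame, log_elements=(kind == "elemental"))
        fits = bic_select(Z, range(1, 6), seed=args.seed)
        pd.DataFrame([{"G": f.G, "model": f.covariance_model, "bic": f.bic,
                       "delta_bic": f._delta_bic} for f in fits]).to_csv(
            args.out_dir / f"bic_grid_{kind}.csv", index=False)
        best = fits[0]
        print(f"{kind}: G = {best.G} ({best.covariance_model}), "
              f"proportions {np.round(best.proportions, 2)}")

    # stage three: habitat-shift ages, if transects are supplied
    if args.transects is not None:
        gm = GrowthModel(l_inf=180.0, k=0.09, t0=-0.5)  # override with Horn's values
        rng = np.random.default_rng(args.seed)
        ests = []
        for tr in oio.read_transects(args.transects):
            for el in ("Sr", "Ba"):
                ests.append(transect_shift(tr, el, gm,
                                           seed=int(rng.integers(2**31)))[1])
        summary = cohort_shift_summary(ests)
        (args.out_dir / "shift_summary.json").write_text(json.dumps(summary, indent=2))
        for el, s in summary.items():
            print(f"{el}: median shift age "
                  f"{'none' if s['median'] is None else round(s['median'], 1)}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
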