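# vtmap3d

Analysis toolkit for 3-D intramural cardiac activation mapping in a
plunge-needle-electrode model of acute myocardial ischemia. The package
covers the full desk-side pipeline:

- **Synthetic data** (`vtmap3d.simulate`, `vtmap3d.ap_simulate`):
  multichannel bipolar electrogram episodes (paced, focal, reentrant,
  VF-onset) with exact ground-truth activation times, Purkinje
  prepotentials, conduction block and band-limited noise; microelectrode
  action-potential traces with injected delayed afterdepolarizations (DADs)
  and triggered activity (TA).
- **Onset detection** (`vtmap3d.detection`): max-|dV/dt| activation marking
  with boxcar smoothing, "good channel" templating, class-specific search
  windows (intracardiac / pacing / VF) and a 65 ms refractory pass with
  recalculation.
- **Ischemia assessment** (`vtmap3d.ischemia`): local-interval bracketing
  around the maximum slope and the ≥45% voltage-drop rule with dV/dt
  confirmation of borderline drops.
- **Activation mapping** (`vtmap3d.mapping`): per-needle layer-consistency
  margins (20/30 ms, growing 2/3 ms per onset), outlier re-sequencing into
  the trend window, and isochrone banding (white < −25 ≤ yellow ≤ 15 < …).
- **Mechanism classification** (`vtmap3d.mechanism`): focal vs reentrant
  complexes (earliest-adjacent-to-latest rule, surround-and-no-return
  rule), Purkinje-origin detection from 0.5 mV / 1–2 ms prepotentials, and
  episode typing (sustained VT / non-sustained VT / VF).
- **Cellular AP analysis** (`vtmap3d.ap_analysis`): MDP/RMP, APA,
  APD50/APD90 extraction, DAD/TA detection and the TA-per-trial rate.
- **Study summary** (`vtmap3d.fixtures`, `vtmap3d.summary`): packaged
  per-dog induction outcome tables (54 dogs, 4 inductions each), the
  category-reproducibility and block-of-induction rules, group tallies and
  2×2 contingency statistics (Pearson chi-square, exact two-tailed
  Fisher).

## Tests

```sh
python -m pytest -q
```

`tests/test_acceptance.py` holds the end-to-end acceptance criteria
(fixture tallies, statistics vs an exact enumeration oracle, detection
recovery on 100 simulated episodes, mechanism-classification accuracy,
ischemia-rule exactness, AP feature recovery).

## Command line

```sh
vtmap3d simulate --mechanism reentry --cycle-length 148 --seed 5 --out bundle/
vtmap3d detect    --in bundle/ --out events.csv          # optional --config cfg.yaml
vtmap3d map       --in bundle/ --events events.csv --out map.csv --plot maps.png
vtmap3d classify  --in bundle/ --map map.csv --cycle-length 148 --out mech.csv
vtmap3d ischemia  --pre pre_bundle/ --post post_bundle/ --out ischemia.csv
vtmap3d ap        --in trace.csv --sidecar trace.json --out features.csv
vtmap3d summarize --group all --out table1.csv
vtmap3d stats     --test chi2 --a APO
```

A recording bundle is a directory holding `meta.json` (grid geometry,
sampling metadata, channel table), `signals.csv` (channels × samples, mV)
and optionally `truth.json` for synthetic recordings.

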