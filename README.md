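# molarmetrics

Automated measurement of the **third-molar maturity index (I3M)** from
two-part instance segmentations of mandibular third molars on panoramic
radiograph crops.

Forensic age estimation frequently hinges on whether a person is a minor:
the I3M method measures, on an orthopantomogram, the widths of the two open
root apices of the lower third molar (*a*, mesial; *b*, distal) and the
tooth height (*c*), and computes

```
I3M = (a + b) / c
```

As the root apices mineralize and close with age, I3M decreases toward 0;
the established cut-off classifies **I3M < 0.08 as adult (≥ 18 y)** and
I3M ≥ 0.08 as minor. `molarmetrics` automates the measurement step: given
one *apical* and one *coronal* polygon mask (the labelme convention), it
aligns the tooth vertically on the barycenter axis and measures a, b, c
with two independent post-segmentation geometries:

* **TDA** (radii partition): root-canal centerlines are found as the
  midlines of background gaps enclosed by the apical mask; rays cast from
  the centerline partition the apical boundary into a pulp–dentine and a
  tooth–environment interface, and each apex width is the distance between
  the two wall extremities where those interfaces meet.
* **TDA-DL** (skeleton end points): an inverted-U medial centerline of the
  apical band supplies left/right apical limit points; the lowest coronal
  pixels on each side of the vertical axis supply coronal limit points;
  a and b are the coronal-to-apical limit-point distances.  The centerline
  backend is pluggable (a learned model can replace the deterministic
  medial-axis default).

The package also ships the evaluation stack used to audit such a tool:
IoU with per-pixel confusion maps (green TP / orange FP / red FN), MAE ± SD,
Pearson correlation, paired t-test, McNemar's test on minor/adult decisions,
and a synthetic-phantom generator with analytic ground truth, so the whole
pipeline is testable without clinical radiographs.

Intended users: forensic odontology researchers and tool builders who need
a reproducible, inspectable I3M measurement back end with explicit
landmarks rather than a black box.

## Worked example

Generate three phantom teeth, measure them with both geometries, and
compare the scores against the generator's analytic truth:

```
$ molarmetrics synth --n 3 --seed 9 --out ds
wrote 3 phantoms to ds

$ molarmetrics measure ds/phantom_*.json --method both --out meas
measured 6 rows, 0 errors -> meas

$ head -4 meas/measurements.csv
source_id,method,a_px,b_px,c_px,i3m,decision
phantom_0000,TDA,18.0,10.017773134657789,168.0,0.16677245913486777,minor
phantom_0000,TDA_DL,23.706539182259394,16.401219466856727,168.0,0.2387366586256912,minor
phantom_0001,TDA,18.0,19.02636220835486,122.0,0.30349477219963,minor

$ molarmetrics compare --computed meas/measurements.csv \
      --reference ds/truth.csv --out cmp
{
  "method": "TDA",
  "n": 3,
  "mae": 0.002853219517200606,
  ...
  "agreement_fraction": 1.0
}
```

Reading the output: `phantom_0000` was generated with apex widths 18 and
10 px and height 168 px; TDA recovers them to within a pixel and scores
I3M = 0.167 → *minor*.  TDA-DL reads its limit-point distances slightly
outside the apex (23.7, 16.4) — it measures at the apical foramen rather
than the constriction, a known systematic overestimate — but the decision
is unchanged.  The `compare` report shows a mean absolute I3M error of
0.003 against truth and full decision agreement.  `meas/overlays/` holds
PNGs with the masks, landmarks, and the a/b/c segments drawn on each crop
so every number can be verified visually.

Every generated phantom carries analytic landmarks (wall-tip pairs, cusps,
top/bottom extremes), so recovered lengths are audited against exact
geometry, not against another measurement.

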