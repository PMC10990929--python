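{
 "manifest_hash": "2fa3a81829676665bb65942b94f7580749d9592ab5ded6250e50c5d4786f7247",
 "seed": 20240101,
 "stages": {
  "classification": {
   "auc_full": 1.0,
   "auc_selected": 1.0,
   "n_samples": 524,
   "n_selected": 5
  },
  "colocalization": {
   "n_pairs": 0
  },
  "cube": {
   "n_features": 418
  },
  "input": {
   "axis_points": 538,
   "n_pixels": 1024
  },
  "offsample": {
   "n_features": 9
  },
  "peaks": {
   "n_peaks": 6270
  },
  "recalibrate": {
   "n_calibrated": 1024,
   "n_pixels": 1024
  },
  "roi": {
   "n_background": 497,
   "n_sample": 527
  },
  "ssim_filter": {
   "n_features": 9,
   "tau": 0.3,
   "w": 0.5
  },
  "unmixing": {
   "final_error": 248.1592221106757,
   "k": 2,
   "n_iter": 175,
   "tissue_component": 0
  }
 }
}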