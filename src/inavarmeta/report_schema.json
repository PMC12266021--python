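{
  "description": "Contract for summary.json written by report.run_pipeline",
  "required": {
    "dataset.n_rows": "int",
    "dataset.column_checksum": "str",
    "counts.total": "int",
    "counts.both": "int",
    "counts.activation_only": "int",
    "counts.inactivation_only": "int",
    "software.version": "str",
    "seed": "int"
  },
  "stages": [
    "fig2.means.activation",
    "fig2.means.inactivation",
    "fig2.sds.activation",
    "fig2.sds.inactivation",
    "fig2.counts.activation",
    "fig2.counts.inactivation",
    "fig3.regression",
    "fig3.fixed_slope",
    "fig3.decomposition",
    "components",
    "fig4.subgroups",
    "fig5"
  ]
}
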