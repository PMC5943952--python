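{
  "viscosity_293K.csv": "0270187f87b3c0cb7575cf0c88b46893377c947917956aa3c18c33797deae9a6",
  "gamma_inf_298K.csv": "e8716e1ccc8885b07f23650ce1a5b7f87effe41b56d43227027723381d005228",
  "viscosity_293K.meta.json": "9fc9eb62d80ec3d62e4b0e38789bd46c8febd24fbda5f625d6ebcb8a8e0b8893",
  "gamma_inf_298K.meta.json": "ed9b67f6605f0d3115721580f1fe5caef02bb6efc26eb0ae5140fa6b855a612f"
}
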