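{
 "table1": {
  "source": "published results table transcription",
  "sha256": "03177361bc1d096984f188cbff1bb8d85b0b80c321094f4e5c8b221277a47e09",
  "n_rows": 31
 },
 "table2": {
  "source": "published results table transcription",
  "sha256": "efb570fc8e72912e1c35c4a14dc6ff846cd3ad7985e43c0e2f145c2ae0369cc9",
  "n_rows": 21
 },
 "table3": {
  "source": "published results table transcription",
  "sha256": "5dfb3f2c6a6b295fc5e64d6ca26c23ca7d7b1912fcba7712472767bdf4a927cf",
  "n_rows": 24
 }
}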