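# Default US CMS-style imaging fee schedule (USD).
ct_fee: 3828
kvpi_fee: 76
mvpi_fee: 76
cbct_fee: 118
igrt_onetime_fee: 440
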