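{
 "V": -78.38403265658346,
 "Na_i": 9.315083556421943,
 "K_i": 140.0,
 "gating": {
  "m": 0.004596428057812935,
  "h": 0.9359800690501573,
  "j": 0.9548210946408754,
  "d": 0.00019389420652300262,
  "f": 0.9993262857094962,
  "b": 0.0005138999094081488,
  "g": 0.8873551036078078,
  "r": 0.03550859915644897,
  "s": 0.9987171154935081,
  "xr": 0.00030116823016542463,
  "xs": 0.0209182504277833
 },
 "Ca_cyto": [
  0.00012949360289025923,
  0.00013056217374133133,
  0.00013116235546141282,
  0.0001315134730816919,
  0.00013172094634856567,
  0.00013184387140105933,
  0.00013191606228876403,
  0.00013195646420897602,
  0.00013197484160913206,
  0.00013197484160913206,
  0.00013195646420897602,
  0.00013191606228876403,
  0.00013184387140105933,
  0.00013172094634856567,
  0.0001315134730816919,
  0.00013116235546141282,
  0.00013056217374133133,
  0.00012949360289025923
 ],
 "Ca_SRS": [
  0.00014500160093873686,
  0.00013256215293380852,
  0.00013206788055630553,
  0.00013234647712438995,
  0.0001325587614014786,
  0.00013268835484385222,
  0.00013276468622778256,
  0.00013280736898214947,
  0.000132826732978207,
  0.000132826732978207,
  0.00013280736898214947,
  0.00013276468622778256,
  0.00013268835484385222,
  0.0001325587614014786,
  0.00013234647712438995,
  0.00013206788055630553,
  0.00013256215293380852,
  0.00014500160093873686
 ],
 "Ca_SR": [
  0.7273876979760625,
  0.7274040634667911,
  0.727466370905377,
  0.7275541378098889,
  0.7276453977804633,
  0.727728594022185,
  0.727798772013216,
  0.7278554758567746,
  0.7278980287269925,
  0.7278980287269925,
  0.7278554758567746,
  0.727798772013216,
  0.727728594022185,
  0.7276453977804633,
  0.7275541378098889,
  0.727466370905377,
  0.7274040634667911,
  0.7273876979760625
 ],
 "Ca_JSR": [
  0.5941370092210434,
  0.5883892623179653,
  0.5870436928570948,
  0.5867139453863021,
  0.5863936958063012,
  0.5860721793276479,
  0.5857340192313304,
  0.5855533439020001,
  0.5869508095340071,
  0.5869508095340071,
  0.5855533439020001,
  0.5857340192313304,
  0.5860721793276479,
  0.5863936958063012,
  0.5867139453863021,
  0.5870436928570948,
  0.5883892623179653,
  0.5941370092210434
 ],
 "cru_open": [
  5.914781174030063e-10,
  4.222266452767393e-10,
  4.155485186479266e-10,
  4.18443416566972e-10,
  4.2054746344309713e-10,
  4.216708458569445e-10,
  4.221581171951496e-10,
  4.22394842677236e-10,
  4.2356917087131167e-10,
  4.2356917087131167e-10,
  4.22394842677236e-10,
  4.221581171951496e-10,
  4.216708458569445e-10,
  4.2054746344309713e-10,
  4.18443416566972e-10,
  4.155485186479266e-10,
  4.222266452767393e-10,
  5.914781174030063e-10
 ],
 "cru_inact": [
  0.17631681688847775,
  0.15041856942941523,
  0.14932761051078763,
  0.15011180651232903,
  0.1508257208067425,
  0.15140244435314823,
  0.15187001105864195,
  0.15221441360485674,
  0.15242782486945483,
  0.15242782486945483,
  0.15221441360485674,
  0.15187001105864195,
  0.15140244435314823,
  0.1508257208067425,
  0.15011180651232903,
  0.14932761051078763,
  0.15041856942941523,
  0.17631681688847775
 ],
 "Ca_junct": [
  0.00038640189320303614,
  0.00038640189320303614
 ],
 "Ca_SL": [
  9.622029408238636e-05,
  9.622029408238636e-05
 ]
}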