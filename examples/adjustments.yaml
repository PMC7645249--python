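# Example currency/inflation adjustment table (synthetic fixture values).
#
# Cost inputs of countries listed under `countries` are converted to EUR
# at the year-average rate of their publication year, then inflated to the
# 2017 price level with the country-specific factor.  Countries not listed
# are assumed to be denominated in EUR-2017 already.
currencies:
  GBP:
    2015: 1.378   # EUR per GBP, year average (illustrative)
  SEK:
    2016: 0.106
inflation:
  UK:
    2015: 1.041   # factor from 2015 prices to 2017 (illustrative)
  SE:
    2016: 1.018
countries:
  UK:
    currency: GBP
    cost_year: 2015
  SE:
    currency: SEK
    cost_year: 2016
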