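# Taxonomy of the 69 features along three axes:
#   category    — physiological/behavioral grouping used for aggregate importance
#   source      — where the raw data comes from
#   engineering — data-driven summary statistic, domain-driven construction, or other
version: 1
features:
  hr_mean:        {category: heart rate, source: wearable, engineering: data-driven}
  hr_sd:          {category: heart rate, source: wearable, engineering: data-driven}
  hr_min:         {category: heart rate, source: wearable, engineering: data-driven}
  hr_max:         {category: heart rate, source: wearable, engineering: data-driven}
  hr_q1:          {category: heart rate, source: wearable, engineering: data-driven}
  hr_q3:          {category: heart rate, source: wearable, engineering: data-driven}
  hr_skew:        {category: heart rate, source: wearable, engineering: data-driven}
  acc_mean:       {category: activity, source: wearable, engineering: data-driven}
  acc_sd:         {category: activity, source: wearable, engineering: data-driven}
  acc_min:        {category: activity, source: wearable, engineering: data-driven}
  acc_max:        {category: activity, source: wearable, engineering: data-driven}
  acc_q1:         {category: activity, source: wearable, engineering: data-driven}
  acc_q3:         {category: activity, source: wearable, engineering: data-driven}
  acc_skew:       {category: activity, source: wearable, engineering: data-driven}
  eda_mean:       {category: electrodermal activity, source: wearable, engineering: data-driven}
  eda_sd:         {category: electrodermal activity, source: wearable, engineering: data-driven}
  eda_min:        {category: electrodermal activity, source: wearable, engineering: data-driven}
  eda_max:        {category: electrodermal activity, source: wearable, engineering: data-driven}
  eda_q1:         {category: electrodermal activity, source: wearable, engineering: data-driven}
  eda_q3:         {category: electrodermal activity, source: wearable, engineering: data-driven}
  eda_skew:       {category: electrodermal activity, source: wearable, engineering: data-driven}
  temp_mean:      {category: temperature, source: wearable, engineering: data-driven}
  temp_sd:        {category: temperature, source: wearable, engineering: data-driven}
  temp_min:       {category: temperature, source: wearable, engineering: data-driven}
  temp_max:       {category: temperature, source: wearable, engineering: data-driven}
  temp_q1:        {category: temperature, source: wearable, engineering: data-driven}
  temp_q3:        {category: temperature, source: wearable, engineering: data-driven}
  temp_skew:      {category: temperature, source: wearable, engineering: data-driven}
  ibi_mean:       {category: stress, source: wearable, engineering: domain-driven}
  ibi_median:     {category: stress, source: wearable, engineering: domain-driven}
  ibi_max:        {category: stress, source: wearable, engineering: domain-driven}
  ibi_min:        {category: stress, source: wearable, engineering: domain-driven}
  sdnn:           {category: stress, source: wearable, engineering: domain-driven}
  rmssd:          {category: stress, source: wearable, engineering: domain-driven}
  nn50:           {category: stress, source: wearable, engineering: domain-driven}
  pnn50:          {category: stress, source: wearable, engineering: domain-driven}
  eda_peaks:           {category: stress, source: wearable, engineering: domain-driven}
  eda_peaks_total_2h:  {category: stress, source: wearable, engineering: domain-driven}
  eda_peaks_mean_2h:   {category: stress, source: wearable, engineering: domain-driven}
  activity_bout:  {category: activity, source: wearable, engineering: domain-driven}
  bouts_total_1h: {category: activity, source: wearable, engineering: domain-driven}
  bouts_mean_24h: {category: activity, source: wearable, engineering: domain-driven}
  acc_mean_2h:    {category: activity, source: wearable, engineering: domain-driven}
  acc_max_2h:     {category: activity, source: wearable, engineering: domain-driven}
  minutes_from_midnight: {category: circadian rhythm, source: wearable, engineering: domain-driven}
  hours_from_midnight:   {category: circadian rhythm, source: wearable, engineering: domain-driven}
  wake_time:             {category: circadian rhythm, source: wearable, engineering: domain-driven}
  calories_2h:    {category: food, source: food log, engineering: domain-driven}
  calories_8h:    {category: food, source: food log, engineering: domain-driven}
  calories_24h:   {category: food, source: food log, engineering: domain-driven}
  protein_2h:     {category: food, source: food log, engineering: domain-driven}
  protein_8h:     {category: food, source: food log, engineering: domain-driven}
  protein_24h:    {category: food, source: food log, engineering: domain-driven}
  carbs_2h:       {category: food, source: food log, engineering: domain-driven}
  carbs_8h:       {category: food, source: food log, engineering: domain-driven}
  carbs_24h:      {category: food, source: food log, engineering: domain-driven}
  sugar_2h:       {category: food, source: food log, engineering: domain-driven}
  sugar_8h:       {category: food, source: food log, engineering: domain-driven}
  sugar_24h:      {category: food, source: food log, engineering: domain-driven}
  eating_event:     {category: food, source: food log, engineering: domain-driven}
  eating_count_2h:  {category: food, source: food log, engineering: domain-driven}
  eating_count_8h:  {category: food, source: food log, engineering: domain-driven}
  eating_count_24h: {category: food, source: food log, engineering: domain-driven}
  eating_mean_2h:   {category: food, source: food log, engineering: domain-driven}
  eating_mean_8h:   {category: food, source: food log, engineering: domain-driven}
  eating_mean_24h:  {category: food, source: food log, engineering: domain-driven}
  sex:            {category: biological sex, source: user input, engineering: other}
  hba1c:          {category: HbA1c, source: user input, engineering: other}
  personalization: {category: personalization, source: model, engineering: other}
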